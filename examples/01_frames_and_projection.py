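"""Frenet frames, backbone angles and the stereographic chart.

Builds an ideal alpha-helix Ca trace, measures its virtual bond (kappa)
and torsion (tau) angles from discrete Frenet frames, and projects them
onto the plane via x + iy = tan(kappa/2) e^{i tau}.  For a regular helix
every interior residue shows the same (kappa, tau), so all projected
points coincide — a single spot in the helical region of the chart.
"""

import numpy as np

from cbrecon import backbone_angles, frenet_frames, stereographic_project
from cbrecon.structio import ChainTrace, Residue

radius, rise, per_turn = 2.27, 1.51, 3.6
i = np.arange(20)
ang = 2 * np.pi * i / per_turn
ca = np.column_stack([radius * np.cos(ang), radius * np.sin(ang), rise * i])
trace = ChainTrace(model_id=1, chain_id="A",
                   residues=[Residue(seq_index=k + 1, res_name="ALA", ca=ca[k],
                                     auth_seq=k + 1) for k in range(20)])

frames = frenet_frames(trace)
angles = backbone_angles(frames)
print(f"valid frames: {int(frames.valid.sum())} of {len(trace)} residues")
k = angles.kappa[angles.valid][0]
t = angles.tau[angles.valid][0]
print(f"helix backbone angles: kappa = {k:.4f} rad, tau = {t:.4f} rad")
print("  (kappa > 1.2 marks the helix-like side of the partition)")

xy = stereographic_project(angles)
print(f"stereographic points: {len(xy)}, all at "
      f"({xy[0, 0]:.4f}, {xy[0, 1]:.4f}) — one spot on the chart")
assert np.allclose(xy, xy[0], atol=1e-9)
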