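"""Build a Cβ-direction library and reconstruct a held-out chain.

Simulates 41 reference chains with planted per-residue-pair Cβ
directions plus angular noise, builds the binned (Δκ, Δτ, Δψ) library
from 40 of them, and reconstructs the held-out chain's Cβ atoms from its
Cα/O trace alone.  The per-residue provenance shows how each prediction
was found (unique pair match, pair average, bin average, or neighboring
bin); deviations are the angles between true and predicted Cα→Cβ
directions.
"""

import numpy as np

from cbrecon import (GeneratorSpec, build_library, deviation_distribution,
                     generate, reconstruct_chain)

spec = GeneratorSpec(n_chains=41, n_residues=60, noise_sigma=0.05, seed=42)
traces = generate(spec)
train, held_out = traces[:-1], traces[-1]

lib = build_library(train)
print(f"library: {lib.n_observations} observations from "
      f"{lib.source_structures} chains in {len(lib.bins)} occupied bins")

result = reconstruct_chain(held_out, lib)
print("provenance:", dict(sorted(result.provenance_counts().items())))

summary = deviation_distribution(held_out, result)
print(f"Ca->Cb angular deviation over {len(summary.deviations)} residues: "
      f"median {summary.median:.4f} rad, peak {summary.peak_location:.3f} rad")
print("  (the planted noise has circular sd 0.05 rad; a held-out median of")
print("   the same order means the library recovered the planted directions)")

radii = [np.linalg.norm(rec.cb - held_out.residues[rec.index].ca)
         for rec in result.predicted_records]
print(f"all predicted Cb sit at {min(radii):.6f}-{max(radii):.6f} A from Ca "
      "(the fixed 1.55 A covalent radius)")
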