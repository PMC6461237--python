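# Methods

This note records the model, the numerical conventions, and the design
choices behind `cbrecon`, in the spirit of a package reference manual.
No empirical claim here goes beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Model and assumptions

The reconstruction treats a protein chain as a Cα polygon with ~3.8 Å
virtual bonds. Two framings are used:

- **Discrete Frenet frames** `(n, b, t)` from three consecutive Cα
  positions; defined wherever both adjacent virtual bonds exist inside
  one unbroken segment and are not collinear. The bond angle κ_i is the
  angle between tangents t_i, t_{i+1}; the torsion τ_i the signed angle
  between binormals b_i, b_{i+1}. Consequently the first and last residue
  of a segment carry no frame, the last two no κ, and the first and last
  two no τ; every eligibility window in the package is derived from these
  rules rather than hard-coded offsets.
- **CαO frames** `(û, v̂, ŵ)` centered on the carbonyl O(i) and spanning
  the virtual peptide plane Cα(i)–Cα(i+1)–O(i).

The central empirical assumption is that the Cβ direction seen from the
Frenet frame is highly localized and determined, to good approximation,
by (a) the local backbone state (κ_i, κ_{i+1}, τ_i), (b) the peptide
plane orientation summarized by the O longitude ψ_i, and (c) the residue
identities at i and i+1. Radial variation is ignored: Cβ is always
placed at 1.55 Å from Cα (and O sits near 2.40 Å from Cα); only the
directional statistics are modeled.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `kappa_threshold` | 1.2 rad | helix-like (κ ≥ 1.2) vs strand-like (κ < 1.2) split; the boundary value goes to the ≥ side |
| `n_tau_sectors` | 60 | τ bins of width π/30 |
| `n_psi_segments` | 90 | ψ bins of width π/45 |
| `cb_radius` | 1.55 Å | Cα–Cβ covalent length at which predictions are realized |
| chain-break window | [2.5, 4.3] Å | accepted Cα–Cα virtual bond; [2.5, 3.3) additionally flagged cis-like |
| collinearity tolerance | 1e-8 | cross-product norm below which a frame is degenerate and marked invalid (never a silent NaN) |

All bins are half-open `[lo, hi)` intervals anchored at −π; values at the
upper boundary wrap into the last bin. The bin widths are fixed by the
partition counts; the anchor at −π is a package convention (only the
widths, not the origin, are dictated by the method).

## Selection cascade and fallback order

A query for (bin, pair) resolves in order: unique pair occupant (used
verbatim), multiple occupants (linear mean of θ, circular mean of ϕ),
pair absent (whole-bin aggregate), bin empty (neighbor fallback). The
neighbor search is deterministic: within the same (Δκ set, τ sector) the
ψ ring is scanned at increasing clockwise offset — *clockwise means
decreasing bin index, wrapping* — and when a whole ψ ring is empty the τ
sector steps clockwise and its ring is rescanned starting from the
original ψ index. The Δκ set is never crossed by the scan; only when an
entire set is empty does the query restart in the most richly populated
other set (logged). The clockwise sign and the no-set-crossing rule are
package conventions chosen for determinism; the underlying method
prescribes a neighbor substitution but not its orientation.

Whole-bin aggregates are always derived from the per-pair cells through
one canonical function (iterating pairs in sorted order), so a freshly
built library and one reloaded from disk answer every query identically.

## Circular statistics

Longitudes are averaged by the resultant-vector mean: X = mean cos,
Y = mean sin, R = √(X²+Y²), mean = atan2(Y, X), canonicalized to
[−π, π). R < 1e-9 (antipodal balance) raises an error in the public
`circular_mean`; inside library cells the mean defaults to 0 with a
warning so that batch builds never abort on a pathological cell.
Latitudes are averaged linearly, mirroring the linear κ averaging of the
underlying method; latitude lives on [0, π] where the linear mean is
well-behaved for concentrated data.

Angle computations clamp arccos arguments to [−1, 1]; angle *between
vectors* uses the atan2(‖a×b‖, a·b) form, which is exact at 0 and π and
well-conditioned for the tiny angles the self-consistency checks probe
(arccos of a dot product cannot resolve angles below ~1e-8).
`sign(0) = +1` breaks the measure-zero τ tie; longitude at the poles is
fixed to 0.

## Ideal peptide plane

The dimensions of the rigid trans peptide unit are a named,
user-overridable parameter set (`engh-huber-1991` by default: Cα–C
1.525, C=O 1.231, C–N 1.329, N–Cα 1.458, N–H 1.00 Å; angles Cα–C–N
116.2°, Cα–C–O 120.8°, C–N–Cα 121.7°, C–N–H 119.2°). The in-plane (û, v̂)
offsets of C, N, H from O are *derived* from these values at run time by
laying the unit out flat (ω = 180°, amide H trans to the carbonyl O);
the derivation reproduces the expected Cα–Cα distance (3.804 Å) and
Cα–O distance (2.401 Å). Sanity windows C–O ∈ [1.15, 1.35] and C–N ∈
[1.25, 1.45] Å reject nonsensical parameter sets at construction.
Cis-like peptides (short virtual bond) keep the trans layout with a
warning — no cis recipe is attempted.

## Synthetic generator

`synthgen` inverts the frame relations: a per-residue (κ, τ) program is
turned into Cα positions by tangent propagation
`t_{i+1} = cos κ_i t_i + sin κ_i (cos τ_i n_i − sin τ_i b_i)`, chosen so
that measuring the generated chain returns the program exactly — this
round trip, not the transfer convention, is the module's contract.
Chains are then decorated with O (2.40 Å, latitude strip π/4 ± 0.08) and
Cβ (1.55 Å) atoms at per-residue-pair planted mean directions, which are
a deterministic function of the seed and the pair names, plus
tangent-plane Gaussian noise wrapped onto the sphere. The noise
parameter σ is the **circular standard deviation** √(−2 ln R̄) of the
resulting directions (per tangent component the Gaussian sd is σ/√2) —
the standard directional-statistics dispersion, verified by a
Monte-Carlo test.

What the generator emulates: the ~3.8 Å virtual-bond geometry, the
narrow O latitude strip, secondary-structure-like (κ, τ) programs
(helix- and strand-side presets, a mixed program, and a random-coil
annulus κ ∈ [1.0, π/2]), residue-pair-specific Cβ directions, and
controllable angular dispersion. What it does not emulate: real
rotamer physics, sterics, correlated backbone/side-chain fluctuations,
sequence composition bias, and the broad multi-basin (κ, τ)
distributions of real proteins. Passing the recovery benchmark therefore
demonstrates that the machinery (binning, averaging, fallback,
placement) recovers planted structure at realistic noise — not that the
method achieves any particular accuracy on real structures.

### Benchmark conditions

The standard benchmark uses 50 chains × 60 residues, noise σ = 0.05 rad,
a 40/10 train/test split by chain index, uniform sampling over the 19
non-glycine residues, and a single helix-side (κ, τ) program. The single
program is deliberate: a reference library built from thousands of real
structures covers the queried bins densely, and at 40 training chains
that density is emulated by restricting program variety so that every
queried bin family is represented in training. Problem sizes throughout
the tests (tens of chains, tens of residues) are chosen to exercise
every code path while keeping the suite fast.

## Degenerate inputs and determinism

Collinear tangents, O on the Cα–Cα axis, zero-length bonds, glycine (no
Cβ), missing atoms and chain termini all resolve to *marked invalid /
skipped with a reason*, never an exception, in batch reconstruction;
each residue carries exactly one provenance label. Reconstruction is a
pure function of (trace, library, options); library building is
insertion-order independent to 1e-12 (floating-point summation is the
only order sensitivity). Peak locations of deviation histograms use the
mode of 0.01-rad bins with ties broken toward the smaller deviation —
a deterministic estimator chosen over KDE on purpose.

## Known limitations

- Glycine has no Cβ; the optional `virtual` mode emits a pseudo-atom for
  coarse-grained pipelines but is off by default.
- Chain termini and break-adjacent residues are never predicted (their
  frames/angles are undefined); no truncated-information extrapolation
  is attempted.
- The fixed 1.55 Å radius ignores residue-specific bond-length
  variation; radial error is reported separately from angular error.
- The library keys on exact residue-pair names; chemically similar pairs
  share information only through the bin aggregate, not through any
  similarity metric.
- mmCIF is read but output is PDB only.
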