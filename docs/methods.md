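# Methods

`docktriage` implements the analysis layer of a structure-based
drug-repurposing screen against the SGLT2–MAP17 glucose transporter complex:
everything that happens *after* a docking engine has produced poses and
scores, and *after* an MD engine has produced ligand-RMSD traces. The four
statistics it owns are (1) the symmetry-corrected pose RMSD used to pick a
docking method, (2) the key-residue contact/H-bond score and overlap used to
filter poses, (3) the enrichment factor of the ranked library, and (4) the
censored replicate-median ligand-RMSD statistic used to validate candidate
poses by short MD runs.

## Units, frames and residue identity

All lengths are Ångström internally. GROMACS-style series in nm are scaled
(×10) at the read boundary, because every threshold in the protocol — 5 Å
contacts, 5.5 Å early stop, 10 Å censor — is quoted in Å. Times are taken as
nanoseconds as written in the input; a series whose time column is in ps must
be converted upstream. Poses and receptor are assumed to share one coordinate
frame (the docking frame); no superposition is ever applied. Residues are
identified by the authored PDB tuple (chain, number, insertion code, name)
with no renumbering, so a key-residue list such as "ASN 75" addresses the
deposited numbering directly.

## Symmetry-corrected pose RMSD

Two poses of the same ligand may differ only by a relabelling of chemically
equivalent atoms; the order-based RMSD then reports a spurious deviation (a
carbon six-ring rotated 60° in place has naive RMSD equal to the 1.39 Å C–C
chord but is geometrically identical). The statistic used here is

    RMSD_sym = min over φ  sqrt( (1/N) Σ_i ‖x_i − y_φ(i)‖² )

where φ ranges over all element- and bond-preserving bijections of the heavy
atoms (graph isomorphisms of the connectivity graphs) and N is the heavy-atom
count. Choices that matter:

* **Heavy atoms only.** Hydrogens are parsed and retained but excluded from
  the statistic, matching common docking-RMSD practice and making the value
  insensitive to whether a tool wrote hydrogens at all.
* **No superposition.** The statistic measures displacement within the
  receptor frame; Kabsch-aligned RMSD answers a different question and is
  deliberately out of scope.
* **Bond orders ignored.** Isomorphism uses connectivity + element only,
  because docking outputs frequently disagree on bond-order assignment for
  the same molecule.
* **Enumeration.** Backtracking search with element and heavy-degree pruning,
  assigning atoms in a most-constrained-first order. A cap (default 100 000
  mappings) guards pathological symmetry and raises an explicit error
  advising a larger cap. The test suite checks exact agreement with an
  exhaustive-permutation oracle on random molecules of ≤ 8 heavy atoms; the
  oracle shares no code with the search.

The benchmark selector simply ranks method labels by this RMSD (ascending,
ties broken lexicographically). It also accepts precomputed RMSD values, which
is how the packaged ten-method re-docking table is consumed.

## Key-residue interaction scoring

A pocket residue *engages* a pose when its minimum heavy-atom distance to a
ligand heavy atom is ≤ 5 Å (the close-contact definition this screen uses; it
is a distance cutoff, not a van-der-Waals radii criterion) or when it forms a
hydrogen bond. The triage quantities over a key-residue list K are

    score   = Σ_{r∈K} ( w_hb·[H-bond] else w_c·[contact] else 0 ),  defaults w_hb = 2, w_c = 1
    overlap = |{r∈K : engaged}| / |K|

The packaged default K is the nine residues lining the gliflozin site within
5 Å of the reference empagliflozin pose: ASN 75, HIS 80, THR 87, PHE 98,
GLU 99, SER 287, TYR 290, LYS 321, GLN 457.

Hydrogen-bond geometry is a package design choice, fully configurable:
donor–acceptor ≤ 3.5 Å, hydrogen–acceptor ≤ 2.5 Å, donor–H–acceptor ≥ 120°.
N and O are donors when carrying a bonded hydrogen and acceptors always
(S excluded by default). When **neither** partner atom has an attached
hydrogen — the typical crystal-structure receptor — the criterion degrades to
the donor–acceptor heavy-atom distance alone (`heavy_atom_fallback`). The
fallback is deliberately *not* applied to pairs where an explicit-hydrogen
test was possible and failed: a bent 90° geometry must not be resurrected by
re-reading the same pair in the hydrogen-free direction. The weighted score
depends on w_hb/w_c, which is why the weight-free overlap is the primary
triage quantity.

## Screen triage and enrichment

Ranking is ascending in score by default (PLANTS-style, more negative =
better), ties broken by compound id so results are order-independent. The top
fraction f keeps N_top = round-half-up(f·N), minimum 1; at N = 877 and
f = 0.01 this gives N_top = 9. The enrichment factor is the standard

    EF_f = (n_a / N_top) / (N_actives / N).

With the four known gliflozin actives all inside the top-1% bin this evaluates
to 877/9 ≈ 97.44. Candidate selection applies three gates in order — docking
score, key-residue overlap, and a user-supplied clinical-inclusion flag — and
records, per compound, the first gate that rejected it. The clinical flag is
an input, not a computation: route of administration and prescription
frequency are analyst judgements.

## MD stability statistic

Per compound, three replicate ligand-RMSD series are processed as:

1. **Early-stop censoring.** From the first frame strictly above 5.5 Å, all
   values are replaced by 10 Å (`censored_from` records the index). Censoring
   runs forward from the crossing rather than erasing the whole replicate:
   the protocol's wording does not fix the scope, forward censoring preserves
   pre-escape information, and both conventions produce identical window
   statistics whenever escape precedes the window; a config flag selects
   whole-replicate censoring.
2. **Replicate median.** Pointwise median across replicates on a shared time
   grid (even counts: mean of the central pair). Slightly offset grids of the
   same length are matched by index with a warning; offsets beyond one frame
   step are an error.
3. **Window median.** Median over frames in the closed interval [9, 10] ns.
4. **Classification and ranking.** Bound iff window median < 5.5 Å
   (*strictly*: exactly 5.5 Å counts as non-binding); compounds rank ascending
   in the window median, ties broken by id.

A replicate that escapes before 9 ns therefore contributes a constant 10 Å
to the window, and a compound whose median series is censored there has
window median exactly 10 Å and classifies unbound.

## Synthetic data: what it emulates and what it does not

The generators produce every input with planted, construction-guaranteed
ground truth:

* **Pockets** place the ligand at the origin with radial "arms" on ≥ 40°
  separated sphere directions (an infeasible-packing error otherwise):
  hydrogen-bond arms are collinear C–C–O–H chains with the receptor acceptor
  oxygen at H···A = 1.9 Å; contact-only key residues put a carbon at
  4.3–4.8 Å; unengaged key residues and decoys sit beyond 7 Å. Contact-only
  and decoy residues contain only carbon, so they cannot hydrogen-bond by
  construction. The ≥ 40° separation bound keeps any cross-arm
  donor–acceptor distance above 3.5 Å, so planted counts are exact.
* **Trajectories** are mean-reverting AR(1) fluctuations (lag-1
  autocorrelation 0.95, stationary standard deviation σ) around a mean μ, on
  a 0.01 ns × 1000-frame grid mirroring the 10 ns protocol. "Stable" series
  are clipped into (0, 5.45] so the early-stop threshold is provably never
  crossed (the generator enforces μ + 4σ < 5.5); "escaping" series add a
  steep linear ramp crossing 5.5 Å at the requested time (jitter ≈ 1 frame at
  default σ = 0.2 Å) and plateau near 8 Å.
* **Screens** draw N uniform scores and plant actives either inside the
  top-f bin (EF exactly (N/N_top)·min(1, N_top/n_actives)) or uniformly
  (EF = 1 in expectation). Overlap and inclusion columns are planted on the
  correct side of recorded gate thresholds, so candidate selection has a
  closed-form answer.

These fixtures validate the *bookkeeping* — detection geometry, censoring,
medians, ranking, gating — not physics. Real pockets have correlated
side-chain geometry, marginal H-bonds and ambiguous protonation; real
trajectories have autocorrelated, non-Gaussian, occasionally re-entering
ligands. Passing the closure suites shows the statistics are computed exactly
as specified, not that the thresholds are optimal for real systems.

## Packaged reference tables

Two small TSVs ship with the package as worked-example inputs: the ten-method
empagliflozin re-docking benchmark (best value 0.765 Å for PLP with a search
radius) and the seventeen-compound MD stability table (window medians 1.54 Å
for empagliflozin, rank 1, through 5.06 Å; the four licensed gliflozins all
below 2 Å). Ingesting printed medians as constant series and re-running the
ranking reproduces the published rank column exactly — a check of the
statistic's conventions (closed window, strict threshold, tie rules), not a
re-simulation. The published enrichment figure of 97.1 at f = 0.01 is treated
as a lower bound: the standard EF formula cannot produce it exactly for any
integer bin at N = 877 (877/9 ≈ 97.44), and no attempt is made to
reverse-engineer the original arithmetic.

## Numerical and scale choices

* Bond perception: bond iff 0.4 Å ≤ d ≤ r_cov(i) + r_cov(j) + 0.45 Å, with
  single-bond covalent radii for the common organic/biological elements;
  unknown elements raise by symbol.
* PDB altloc policy: highest occupancy wins, ties resolve toward altloc 'A';
  multi-record ligand files take the first molecule with a warning.
* Determinism: every generator is a pure function of (seed, parameters);
  reports contain no timestamps, so a rerun with the same config and seed is
  byte-identical.
* Test/validation problem sizes: closure suites use 50 seeded fixtures per
  statistic, 100 random molecules for the symmetry oracle, and
  500-frame/0.02 ns trajectory grids for pipeline-level runs (same
  statistics as the 1000-frame default at half the frames).

## Known limitations

* Hydrogen-bond typing is geometric only — no protonation-state inference,
  no π-stacking, salt-bridge or halogen-bond classes, no per-atom energies.
* The MOL2/SDF readers take the structures as written (`sanitize=False`);
  valence errors in inputs are not repaired.
* The stability stage consumes precomputed RMSD series; computing per-frame
  ligand RMSD from raw trajectories (including whether to superpose the
  protein first, or to symmetry-correct per frame) is upstream of this
  package and both recipes are compatible with its inputs.
* Mapping enumeration is exponential in highly symmetric molecules; the cap
  turns that into an explicit error rather than an unbounded search.
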