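# Methods

## Problem setting

Gas-cluster ion beam (GCIB) SIMS of an undigested protein film produces
singly charged peptidic secondary ions: N-terminal (a, b, c) and
C-terminal (y, z-type) fragments plus abundant internal fragments
(yb/ya/yc-type, from two backbone cleavages), predominantly as sodium
adducts in positive polarity and as deprotonated ions (a, b, c, y, z−H,
x) in negative polarity. Because consecutive members of one fragment
family differ by exactly one residue mass, a high-accuracy mass analyser
turns the spectrum into a readable ladder. The package implements the
full chain from peak list to ranked protein identification, plus the
simulation and profiling machinery needed to validate it.

## Mass arithmetic

All constants come from the pyteomics NIST tables. A fragment ion's m/z
is `sum(residue masses) + series offset + adduct delta` (singly charged
only; no multiply charged species are modelled). Series offsets are
stored relative to b (offset 0) and y (offset +H₂O) with the standard
relations a = b − CO, c = b + NH₃, x = y + CO − H₂, z = y − NH₃,
z+1/z+2 = z + 1/2 H; internal yb-type ions have offset 0 and ya / yc /
ya−NH₃ are −CO / +NH₃ / −CO−NH₃. Adduct deltas include the electron
mass (+H: +1.00728, +Na: +22.98922, −H: −1.00728), so values are
physically exact; note the +Na/+H gap is (Na − e) − proton =
21.98194 Da, which differs from the Na − H *atomic* difference by the
~1.5e-8 Da electron binding energy.

The default residue table holds the 20 standard residues with I/L
collapsed into the ambiguous group `J` (exactly isobaric); K and Q stay
distinct (36 mDa apart, far beyond any window used here). Optional
variants: hydroxyproline `Hyp` (P + O, the collagen marker),
methoxyproline `Mep` (P + CH₂O), and the cysteine disulfide-cleavage
products `C+S` / `C-SH2`. Tables reject residue pairs closer than the
two-sided merge window (2 ppm at a 1000 Da reference) unless grouped.

## Tolerance conventions

Two distinct windows derive from the single ppm tolerance (default
2 ppm, the analyser's accuracy class):

* **absolute peak matching** (ion annotation, targeted profiles,
  common-peak comparison) uses the relative window at the peak's own
  m/z — `tol · mz / 1e6`;
* **ladder-step (gap) matching** uses a constant absolute window,
  the ppm tolerance evaluated at a fixed reference m/z of 1000
  (2 ppm → ±2 mDa), and step errors are reported on that same scale.

The constant gap window is the deliberate design choice. A gap between
two ~1000 Da peaks measured at 1 ppm each carries ~1.4 mDa of combined
uncertainty, so a window tied to the tiny residue mass itself
(2 ppm of ~100 Da = 0.2 mDa) would reject almost every genuine step; a
window tied to the peak m/z would make edge decisions depend on which
adduct carries the fragments (the same gap sits at a 22 Da heavier
absolute position under +Na than +H, and near-boundary coincidences
then flicker). The constant window keeps K/Q unambiguous at any mass,
tolerates the expected jitter, and makes the residue-difference graph
*provably identical* under a global adduct exchange.

## Filtering

Intensity filtering supports absolute, percentile (default 60th, aimed
at the low-intensity background hump of real SIMS spectra) and
median-multiple thresholds. Chemical filtering defaults to
difference-participation: keep exactly the peaks having ≥ 1 partner at
a residue-mass gap. Because that is the precondition for membership in
any ladder, the filter cannot remove signal used downstream, and since
the partner relation is symmetric it is idempotent. A Kendrick-style
mass-defect band filter (slope 0.00048 per Da, half-width 0.25 Da) is
available as a secondary mode. On simulated spectra the validation
pipeline applies only the chemical filter: simulated signal and noise
intensities are both exponential draws with no background structure,
so an intensity cut would only thin the signal.

## Tagging

The residue graph connects every peak pair whose gap matches a residue
mass within the step window (edges point low → high m/z, hence the
graph is acyclic); candidate partners are located by binary search per
residue, not an all-pairs scan. Tags are the maximal paths, deduplicated
and ranked by (steps desc, mean |ppm| asc, residue string asc); a
per-node branch cap (8) and a global cap (5000 tags) bound pathological
dense spectra, logged when hit. Steps matched by several residues
become bracketed alternatives expanded at search time. Tag direction is
left unknown: a ladder read low → high m/z is N→C for N-terminal
series and C→N for C-terminal series, so the database search tries both
orientations.

Maximal paths can be chimeric: overlapping fragment families generate
genuine edges in both sequence directions (C-side extension within a
family, N-side steps between families at adjacent anchors), and a path
mixing the two spells no protein substring. Such tags simply match
nothing in the database; identification rests on the pure sub-ladders,
which are abundant. This is the standard failure mode of offset-free
ladder reading and the reason scoring requires exact full-tag matches.

## Identification and scoring

Tags are searched as exact substrings (regex with overlapping matches,
bracketed steps as character classes) of I/L-collapsed database
sequences, in both orientations; `X` in a database sequence matches no
tag residue. Scoring has no published reference, so the package's own
formula is deliberately simple and flagged here: each distinct matched
tag contributes `max(L − 2, 0)` points, doubled when the tag matches no
other database protein **and** has ≥ 5 steps; ranking breaks ties by
coverage then identifier; the top hit is flagged ambiguous when the
runner-up is within 10% of its score, and an identification is called
unambiguous only when the top protein owns a protein-unique tag of
≥ 8 steps — chosen because a protein is pinned down by one tag exactly
when it owns a k-mer unique in the database, and at k = 8 essentially
every protein does (the `kmer_uniqueness` analysis measures this
fraction for any database). Coverage is the rounded-half-up percentage
of residues in the union of matched positions. The common-peak fraction
between two spectra uses greedy nearest-neighbour pairing, each partner
peak usable once, percentage rounded half-up. Reversed-sequence decoy
generation is available for chance-match estimation but off by default.

## Simulator

The generator is built around fragment *families*: the experimentally
motivated mechanism behind ladders is sequential single-residue loss
from a common cleavage product, so an observed family contributes a
contiguous run of windows sharing one anchor and one adduct. Candidate
families are one per terminal series (prefixes/suffixes) plus a random
sample of interior anchors (0.5 per residue per internal series); each
family is observed with probability `sampling_fraction` × relative
abundance (default 0.25); the run covers ≥ 3 of the admissible 2–15
residue lengths. Emitted fragments get multiplicative Gaussian ppm
jitter (sd 1 ppm), exponential intensities (mean 100), and Poisson
chemical noise is added uniformly over the 150–2250 m/z range
(2 peaks / 100 Da, exponential mean 10). Defaults follow the observed
fragment taxonomy: series (b, y, a, c, z+1, internal-yb, internal-ya),
adduct mix 0.8 +Na / 0.2 +H; negative polarity switches to −H with
series (a, b, c, y, z−H, x). Intensity laws and the anchor density are
this package's own realistic choices — no empirical fragment-frequency
distribution is published for GCIB spectra.

Randomness is split into independent streams (family selection, adduct,
jitter, noise, intensity) spawned from one seed, so changing the adduct
mix alone cannot change which fragment windows are sampled — this is
what lets the adduct-invariance check compare literally the same
fragment set under +H and +Na.

What the simulator does **not** emulate: isotope envelopes, multiply
charged ions, detector saturation, matrix effects, correlated chemical
background (noise fractional masses are uniform, unlike real organic
background which also clusters on the defect line), or any physical
sputtering model. Passing recovery tests therefore demonstrates the
correctness of the ladder/search/scoring machinery under realistic
mass-error statistics, not performance on real instrument data.

## Depth profiling

A targeted profile sums, per scan, the intensities within tolerance of
each marker m/z (e.g. PO₃⁻ at 78.95905 as a phospholipid layer marker;
a built-in preset provides hydroxyproline/methoxyproline collagen
markers). Layer boundaries are placed where the 3-point moving-average
smoothed marker crosses a threshold fraction (default 0.5) of its
maximum. Threshold crossing was chosen over changepoint methods because
the reference workflow assigns layers qualitatively from marker
abundance; the smoothing window is edge-truncated so a clean step stays
a ramp of the same height.

## Validation experiments

`orbitag.experiments` packages the seeded end-to-end protocols used by
the test suite and `scripts/acceptance.py`: complete-series recovery
(noiseless b-series of random 20-mers must yield residues 2–19 as the
single longest tag), parameter recovery (simulated lysozyme vs 100
random decoys, 50 trials), mixture deconvolution (equimolar lysozyme +
insulin both in the top 2, 20 trials), noise-only negative control (no
unique ≥ 8-step identification, 50 trials), exact adduct invariance,
and two-layer depth segmentation within ±1 scan (20 trials). Problem
sizes (100-decoy databases of 100–400-residue sequences, 129- and
51-residue targets) keep each experiment in the seconds-to-a-minute
range while leaving the chance-match statistics realistic. The embedded
insulin target concatenates the B and A chains into one 51-residue
string — a synthetic convenience, as the real hormone is two
disulfide-linked chains.

## Known limitations

* Exact full-tag matching cannot credit a long chimeric tag for its
  correct sub-ladder; a subpath-aware search would recover more signal.
* Scoring and the ambiguity flag are this package's own constructs;
  absolute score values are not comparable across databases of very
  different size without the decoy option.
* The unique-8-mer fraction of small random databases is ~100%, higher
  than curated proteomes with gene families; identifiability claims on
  real databases should re-run `kmer_uniqueness` on those databases.
* mzML support covers the centroided 64/32-bit-float subset only.
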