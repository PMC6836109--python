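# Methods

This note records the model behind `mzsim`, the parameters that matter,
the numerical conventions, and the deliberate design choices made where
the behavior of a real instrument or of upstream tools leaves the design
open.

## The simulation model

A *chemical object* is the unit of signal. A **known chemical** (the
synthetic-sample workflow) carries a molecular formula, a starting RT, a
maximum intensity, a normalized chromatogram template, adduct and isotope
proportions, and a list of (m/z, relative intensity) fragment peaks. It
emits one MS1 trace per adduct × isotope combination at

    mz   = (monoisotopic mass + k·Δ13C + adduct shift) / charge
    I(t) = max_intensity · adduct_prop · isotope_prop · rel(t − start_rt)

where `rel` is the chromatogram's relative-intensity profile. Adduct
proportions sum to 1 and isotope proportions sum to 1, so total trace
proportions sum to 1 and the summed apex intensity equals
`max_intensity`. An **unknown chemical** (the existing-sample workflow,
one per extracted ROI) emits a single trace at its observed m/z.

The **virtual mass spectrometer** keeps a clock and a scan log. A
controller supplies scan requests; for each request the instrument
evaluates all currently eluting chemicals at the clock RT, assembles a
centroided spectrum, stamps it with the clock, and advances the clock by
a scan duration drawn from the spectral feature database for the
(previous level → next level) transition. Chromatograms are stored as
discrete knots; between knots both relative intensity and m/z offset are
linearly interpolated (exact at knots, zero outside the template span).
Fragmentation (MS2) requests carry an isolation window; every chemical
with an eluting trace inside the window contributes its full fragment
list scaled by that trace's current MS1 intensity, so co-isolated
chemicals produce chimeric spectra. An empty window still yields (and
logs) an empty scan — that is the cost of a mis-scheduled acquisition.

### Controllers

* **MS1** — survey scans only.
* **Top-N DDA** — each duty cycle: one MS1 scan, then MS2 scans for up to
  N precursors in descending intensity, subject to (i) a minimum MS1
  intensity, (ii) no match against an active dynamic-exclusion record,
  and (iii) mutual separation above the exclusion tolerance within one
  cycle (so a cycle cannot fragment the same m/z twice). An exclusion
  record (m/z, scan RT + DEW) is added when each MS2 scan completes and
  purged lazily. Because exclusion is checked at selection time and the
  MS2 scan always happens after selection, two fragmentation events on
  matching m/z are always at least DEW seconds apart.
* **Multi-sample prioritization (DsDA-style)** — works on a fixed timing
  grid (repeating cycle of one MS1 slot plus N MS2 slots, constant
  durations set to the feature-database medians). Sample 1 runs DDA on
  the grid. After every sample, MS1 features are picked from the log,
  aligned to a running cross-sample feature list (10 ppm centers,
  overlapping RT), and each feature is scored

      weight = max MS1 intensity × (1 − best MS2 quality so far),
      quality of one MS2 scan = min(1, peaks above noise floor / k_ref)

  with `k_ref = 10` and noise floor 100 counts by default. MS2 slots of
  the next sample are then assigned, slot by slot in time order, to the
  eligible feature (RT box containing the slot) of highest weight —
  greedy by default, weighted-random when MaxDepth is on, which restores
  probability mass to rare low-weight features. Each feature takes at
  most one slot per sample. This scoring is a documented surrogate for
  the original external prioritization script; it reproduces the
  qualitative behavior (prioritize intense, unfragmented or
  poorly-fragmented features) and is swappable.

### Fragment-spectrum generators

Spectrum size is drawn from the empirical per-scan fragment-count pool.
The *random* generator draws peaks independently (with replacement) from
the MS2 peak pool. The *truncated CRP* generator reuses a previously
served peak with probability `count / (total + α)` and opens a new peak
with probability `α / (total + α)` (α = concentration, default 1.0,
user-configurable), never serving the same peak twice within one
spectrum; peaks excluded by that truncation have their probability mass
renormalized over the remaining peaks plus the new-peak mass. New peaks
are drawn uniformly from pool members without a table (falling back to
any unserved-in-this-spectrum member). Fragment m/z values are not
constrained below the precursor by default; a `max_mz` cap is exposed.

### ROI extraction

Centroids at or above a point-intensity threshold are grouped into
regions of interest: a point joins the open ROI whose running mean m/z is
nearest among those within `mz_tol_ppm` (ties to the earlier-created
ROI); the window is re-evaluated after every insertion. At most one point
per ROI per scan — the closer of two same-scan claimants wins and the
loser seeds a new ROI. ROIs not extended by a scan are closed
immediately (the strictest reading of close-on-miss; one missed scan
terminates a trace), and closed ROIs shorter than `min_points` are
discarded. Normalization subtracts the mean m/z (this is the
interpretation of "centered on 0" consistent with the running-mean
matching rule), subtracts the first RT, and divides by the maximum
intensity.

### Evaluation

Picked MS1 features are boxes in m/z × RT with an apex intensity.
Cross-file correspondence: m/z centers within 10 ppm and overlapping RT
ranges, matched greedily by ppm distance, one-to-one. A feature is
*fragmented* when some isolation event lies inside its box (closed
intervals on both axes) with precursor intensity at or above the minimum
MS1 intensity. Ground truth = features found in both files. Then TP =
ground-truth features fragmented above threshold; FP = frag-file-only
features fragmented above threshold; TN = frag-file-only features not
fragmented above threshold; FN = full-scan-only features **plus** —
a documented extension — ground-truth features not fragmented above
threshold. The printed four-cell scheme does not cover that last cell;
without the extension, recall = TP/(TP+FN) would ignore exactly the
features a strategy failed to fragment, so the extension is what makes
recall a coverage measure of the ground truth.

The bundled "naive picker" (ROI extents + apex filter, default
min_points = 4) exists for tests and for the prioritization loop;
external picked-peak CSVs are the intended input for real analyses.

## Tunable parameters

| parameter | default | units | role |
|---|---|---|---|
| `TopNParams.N` | 10 | – | fragmentation events per duty cycle |
| `TopNParams.dew` | 15 | s | dynamic exclusion window |
| `TopNParams.min_ms1_intensity` | 1.75×10⁵ | counts | precursor selection threshold |
| `TopNParams.isolation_width` | 1.0 | Th | full isolation-window width |
| `TopNParams.mz_tol` | 0.01 | Th | exclusion matching tolerance (ppm optional) |
| `ROIParams.mz_tol_ppm` | 10 | ppm | ROI matching half-window |
| `ROIParams.min_points` | 3 (picker: 4) | – | minimum trace length |
| CRP `concentration` | 1.0 | – | new-fragment propensity |
| replicate `noise_sd` | 10⁴ in benchmarks | counts | intensity jitter between replicates |
| replicate `dropout_prob` | – | – | per-sample chemical dropout |
| DsDA `k_ref` / noise floor | 10 / 100 | peaks / counts | MS2 quality surrogate |

Defaults follow common orbitrap metabolomics settings (DEW 15 s, minimum
intensity 1.75×10⁵, 1 Th isolation).

## What the synthetic fixtures emulate — and what they do not

Fixture databases draw MS1 feature m/z uniformly over 70–1000 Th, log10
apex intensity uniformly over [4, 7], fragment counts uniformly over
5–30, and scan durations near 0.4 s (MS1) / 0.2 s (MS2) with ±10%
jitter — the scan economics of an orbitrap platform. Chromatograms are
Gaussian with σ between 3 and 10 s and carry a small (0.2 mTh) m/z
wobble. Formula pools are random CHNOPS compositions (thousands of
mostly distinct monoisotopic masses, like a metabolite-database export).

Benchmark-scale runs in the test suite use 200–500 chemicals starting in
a 10–60 s RT window and an 80 s acquisition. That RT packing keeps the
instrument *precursor-limited* — there are always more eligible
precursors than MS2 capacity, as on real complex samples — which is the
regime where the Top-N trade-off and the multi-sample prioritization
comparison are meaningful; the small absolute window simply scales the
experiment down. Problem sizes for the end-to-end checks: 10,000
chemicals for the dropout law, 500 for the F1-versus-N curve (N ∈ {1, 2,
5, 10, 20, 50}) and the 5-sample prioritization benchmark (5 seeds).

Deliberately **not** modeled: profile-mode peak shapes,
resolution/peak-width dependence on m/z, electronic noise baselines,
ion-injection-time dynamics, retention-time drift between replicates,
and instrument stochasticity (real instruments occasionally fragment
below threshold or skip eligible ions). Passing tests therefore
demonstrate correctness of the acquisition logic and the direction of
strategy comparisons, not quantitative agreement with any particular
instrument.

## Numerical conventions and degenerate inputs

* Scan RT stamp = clock at scan start; the duration advances the clock
  afterwards. The first scan of a run samples its duration from the
  (level, level) self-transition of the requested level.
* A missing duration transition falls back, with a warning, to the
  pooled durations of all transitions ending at the requested level.
* Intensity ties in Top-N selection break toward lower m/z; ROI claim
  ties break toward the earlier-created ROI; template choice for a
  synthetic chemical is nearest-neighbor in log10 apex intensity (first
  match on ties).
* Co-eluting traces that collide in m/z within machine precision remain
  separate centroids; no merging.
* Gaussian intensity noise on replicates is floored at 1 count.
* Undefined evaluation ratios (0/0) are reported as 0 and flagged.
* Empty inputs: an empty scan list yields no ROIs; a run with a single
  scan contributes no durations; building a database from no runs is an
  error; an MS1-only corpus builds with a warning and empty MS2 pools.
* The feature database persists as versioned JSON (floats survive the
  round trip exactly); simulator snapshots (scan log, clock, RNG state,
  controller exclusions) likewise.
* All stochastic steps take a `numpy.random.Generator`; identical seeds
  give identical scan logs byte for byte.

## Known limitations

* The DsDA-style controller is a surrogate: its MS2 quality score and
  slot assignment reproduce the prioritization *principle*, not the
  original implementation's numerics.
* MS1 feature sampling from the database is joint per feature
  (m/z, RT, intensity kept together); whether attributes should be
  sampled independently is left open, and joint sampling was chosen as
  the conservative option.
* The naive picker is not a peak-shape-aware picker; counts of "picked
  features" from it are only comparable within a simulation, not with
  XCMS/MZmine output on real data.
* Cross-sample feature alignment is tolerance matching, not retention
  alignment; it is adequate for the simulator's drift-free replicates.
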