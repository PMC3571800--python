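# Methods

## Duplex thermodynamics

Probe–target, primer–template and blocker–template stability is modeled
with nearest-neighbor thermodynamics: the duplex enthalpy/entropy is the
sum of doublet stacking terms from the unified Watson–Crick parameter set,
duplex initiation terms (with the A·T terminal penalty), and published
internal-mismatch doublet parameters for single non-canonical pairs. The
tables are taken from Biopython's `Bio.SeqUtils.MeltingTemp` data
(`DNA_NN4`, `DNA_IMM1`); the summation, salt correction, melting
temperature and occupancy math are implemented here, and Biopython's
`Tm_NN` serves only as an independent cross-check in the test suite
(perfect-match agreement < 0.01 °C).

Two-state melting gives `Tm = ΔH / (ΔS + R·ln(CT/x)) − 273.15`, with
`x = 1` for a probe in excess over its target (the default — detection
probes are in excess over amplicon during melt analysis) and `x = 4` for
equimolar strands. A single monovalent correction `ΔS + 0.368·(N−1)·ln[Na⁺]`
is applied; divalent ions are out of scope. Occupancy is the
pseudo-first-order binding isotherm `θ = K·CT/(1+K·CT)` (probe excess) or
the exact root of the bimolecular quadratic (equimolar); both equal ½ at
their respective Tm.

Defaults: `monovalent_salt = 1.0 M` (the reference condition of the
parameter tables — temperatures are therefore on the 1 M Na⁺ scale and
would read some degrees lower in a real PCR buffer), `strand_conc = 2 µM`
(a typical detection-probe concentration; it also keeps every 6–60-mer
duplex Tm inside the documented [−20, 120] °C range, which the weakest
all-AT hexamers would leave at sub-micromolar concentrations).

Deliberate simplifications, each chosen conservatively:

* at most **3 mismatches** per duplex; beyond that the two-state model is
  untrustworthy and the code raises instead of extrapolating;
* **terminal mismatches are unstacked ends** (no stack, no terminal
  initiation term). Published terminal-mismatch parameters are sometimes
  *stabilizing*, which would let a terminal substitution raise the
  predicted Tm; the unstacked accounting keeps every substitution
  destabilizing, which is what short-probe melt assays rely on;
* adjacent (double) mismatches contribute no stack — no published doublet
  exists for them;
* dangling ends, fluorophore contributions and secondary structure are
  ignored.

A junction-spanning oligo on a template carrying a deletion cannot form a
contiguous duplex; its state is modeled as the most stable **end-anchored
exact fragment** (prefix or suffix, ≥ 6 nt) laid on the template. This is
what gives a deletion allele its strongly shifted low-temperature peak and
a wild-type blocker its collapse of affinity on the deletion allele.

A domain note on mismatch monotonicity: with these tables, a single
substitution strictly lowers Tm for every duplex melting below ~74 °C
(verified by ~3 million randomized comparisons). Hotter duplexes can show
tiny Tm *increases* when a substitution removes a weak stack whose own
ΔH/ΔS ratio lies below the duplex Tm. Probes that hot are unusable on the
40–85 °C melt grid anyway, so the designer caps the match Tm at 72 °C for
point-mutation probes, and the monotonicity property is guaranteed (and
tested) on that designable domain.

## Fluorescence model and peak recovery

Quenching releases on melting, so
`F(T) = b₀ + b₁·(T − Tmin) + A·Σₐ wₐ·(1 − q·θₐ(T)) + ε`, with quench
efficiency `q = 0.85`, amplitude `A = 1` (normalized — amplicon yield is
not propagated into signal strength), allele weights `wₐ` from the
amplicon pool, linear baseline drift `b₁ = 0.002 a.u./°C`, per-sample
amplitude jitter (CV 3 %) and additive Gaussian noise
`σ = 2×10⁻⁴ a.u.` (committed by the one-shot calibration described
below). Melting transitions are therefore peaks in **+dF/dT** — note the
sign; intercalating-dye convention is −dF/dT. The default grid is
40–85 °C in 0.1 °C steps.

Differentiation is a Savitzky–Golay filter (window 15 points, cubic,
first derivative; edge half-windows trimmed), a declared stand-in for the
instrument's undisclosed algorithm. Peak detection takes height and
prominence thresholds as fractions of the global derivative maximum
(germline 0.10/0.05; somatic 0.010/0.008) with 2 °C minimum separation;
equal-height plateaus report their lowest-temperature grid point.

## Genotype calling and mutant-fraction estimation

Detected peaks are assigned to the nearer of the assay's two expected
melting temperatures within a ±2 °C tolerance, one peak per expectation;
a peak equidistant from both (within 0.5 °C) is unresolvable and yields
`no_call`; surplus peaks lower the confidence (assigned prominence over
total prominence) without forcing a no-call. Germline: match-only →
homozygous for the probe-matched allele; mismatch-only → the other
homozygote; both → heterozygous.

The mutant fraction of an amplicon pool is estimated by **nonnegative
regression unmixing**: the observed derivative is fitted as
`w_w·c_w(T) + w_m·c_m(T) + b` where `c_a(T) = −dθₐ/dT` are the pure-allele
melt components known from the assay's duplex thermodynamics and `b`
absorbs baseline drift; the estimate is `w_m/(w_w+w_m)`. This was a
genuinely open design point, settled by three failure modes of the naive
windowed-area ratio: (i) a sharp match peak and a broad mismatch peak have
different window capture, biasing a 50/50 mixture to ~0.6; (ii) in an
*empty* window, clipped noise accumulates into a positive floor that
produces blank false positives; (iii) a minor component on the shoulder of
a neighboring transition contributes area but no local maximum. The
regression estimator is exact for noise-free mixtures at every fraction
(so the calibration map defaults to the identity; a fitted monotone
calibration remains available and is recorded in reports when used), and
its blank-noise scale is ~3×10⁻⁴, giving ~60σ of separation from the
somatic detection threshold. A windowed chord-baseline estimator,
normalized by per-assay capture coefficients, remains as the fallback when
only bare Tm expectations are available.

**Somatic detection is quantitative**: `mutant_detected` requires the
estimated mutant share to reach **0.02** on a curve with at least one
detected melt peak. A single-mismatch minor component below ~15 % of the
pool *never* forms a distinct +dF/dT local maximum under this model — the
mismatch tail under the match peak is `exp(−ΔΔG/RT)`, which probe length
cannot change — so demanding a distinct mutant peak would make unenriched
few-percent detection physically impossible; the enrichment chemistries
are read, as in practice, through the correlation of fluorescence
intensity with mutant proportion. A mutant-side peak whose area share is
below threshold (baseline ripple) stays `wild_only`.

## PCR kinetics

`N_a(c+1) = N_a(c)·(1 + E_a·s(c))` with shared-resource saturation
`s(c) = max(0, 1 − N_tot/K)`, `K = 10¹²` copies — both alleles draw on
one reagent pool. Efficiencies come from primer thermodynamics at the
annealing temperature: `E = e_max·θ(T_anneal)·penalty`, `e_max = 0.95`,
with the 3′-terminal-mismatch penalty applied when the primer's last base
does not pair. In MBP mode each template amplifies at the better of its
two competing primers (competition-winner approximation; the minor
cross-extension path that would convert wild template into
mutant-sequence amplicon is not tracked). In WIP mode the allele-neutral
forward efficiency is scaled by `(1 − blocker occupancy)`, occupancy
being mass-action binding `K·C_b/(1+K·C_b)` at the blocker concentration
(default 2.5 nM). Unbiased (standard) mode anneals at the shared primer's
own optimum and amplifies both alleles identically — composition is
preserved to machine precision. Stochastic mode replaces the expected
per-cycle duplication with binomial draws of the same mean; template
copies are integers and no loss mechanism exists, so trajectories are
non-decreasing.

## Limit-of-detection experiments

Each ladder level builds a template mix of **1,500 copies total** (the
genome-equivalent scale of a few-mL plasma or small purified-DNA input;
mutant copies are rounded, so the 0.03 % level of the deletion ladder
contains zero mutant molecules — the sampling floor that terminates the
deletion assay's sensitivity), then runs `replicates` independent
PCR → melt → somatic-call pipelines. Randomness derives from one master
seed: `numpy.random.SeedSequence(seed).spawn(levels×replicates)`, child
`i·replicates + r` driving replicate `r` of level `i` (PCR draws and melt
noise share the child generator). LoD is the lowest fraction whose
detection rate, and that of every higher fraction, reaches 95 %, provided
the blanks show zero false positives; otherwise it is undefined and
flagged, never silently skipped.

### The committed calibration

Per the one-shot calibration protocol, four knobs were tuned **once**
against the two packaged enrichment fixtures and then frozen:
`extension_mismatch_penalty = 0.90`, `sigma_additive = 2×10⁻⁴`,
`blocker_conc = 2.5 nM`, template input 1,500 copies (with
`e_max = 0.95` kept at its default). The penalty is explicitly an
*effective* per-cycle bias, not a literature extension rate: the
simulator tracks no polymerase error or mispriming, so a realistic
(strong) 3′-mismatch penalty would let the mutant lineage outgrow
essentially any input and push the simulated sensitivity far past what
the omitted error processes bound in reality. With the committed values
the mutation-biased assay enriches a 0.3 % input (4 molecules) to ~3.6 %
of the final pool — comfortably above the 2 % detection threshold — while
0.1 % (2 molecules) reaches only ~1.8 %; the blocker assay suppresses
wild amplification almost completely, so its floor is the template
sampling limit at 0.1 %; and unbiased PCR preserves composition, placing
its floor at the 3 % ladder level, tenfold above the biased assay.

## Assay design rules

* **Probes**: candidate windows on either strand, either labeled end,
  whose labeled terminus is a C pairing a target G and whose footprint
  covers the variant (or strictly spans the deletion junction). Scored by
  the match–mismatch Tm gap, subject to: mismatch Tm ≥ 45 °C (keeps the
  mismatch peak on the grid — the operational form of "too short and the
  mismatch peak vanishes"), match Tm ≤ 72 °C for point mutations
  (≤ 78 °C for long junction probes), and an analytic resolvability
  requirement — the Tm gap must exceed 1.2× the mean analytic
  half-height width `3.53·RT²/|ΔH|` of the two peaks, without which a
  heterozygote melts as one merged peak. Ties break deterministically:
  shortest, lowest start, plus strand, preferred (3′) label.
* **MBP primers**: both allele-specific primers end 3′ on the variant;
  the mutant primer is 5′-extended by 4 nt; annealing is set 5 °C below
  the mutant primer's Tm; a shared reverse primer places the amplicon as
  close as possible to 100 bp (hard bounds ±25 %).
* **WIP blockers**: wild sequence spanning the deletion junction, flanks
  ≥ 8 nt growing until the blocker melts ≥ 5 °C above the annealing
  temperature (cap 40 nt), placed between the primers on the extension
  path; treated as non-extendable.

## Synthetic fixtures

Fixtures are random 400 bp references with the catalog variant embedded
at the center (deletion fixtures add a GC-rich patch left of the junction
so the junction probe's partial duplex stays on the melt grid), designed
end-to-end by the design module; infeasible draws are redrawn from the
same seeded stream, so a fixture is a pure function of (locus, seed).
They emulate the *geometry* of real assays — variant classes, probe and
primer placement, melt-peak structure — but not real genomic sequence,
cross-reactivity, secondary structure, polymerase artifacts or
multi-channel optics. Passing tests therefore validate the measurement
model and its pipelines, not performance on any real specimen.

## Numerical and degenerate-input choices

NaN is the "no melting in range" sentinel (never an exception);
occupancy exponentials are clipped at ±700 before `exp`; zero total
template is an error while a saturation capacity below the input is a
flagged immediate plateau; an empty peak list is a valid result;
fraction estimates are absent (`None`), not zero, when there is no melt
signal; ladder levels must include the blank. Melt curves regenerate
bit-identically from equal seeds, and all multi-replicate experiments
derive child seeds deterministically from the master seed.

## Known limitations

Single fluorescence channel; no hairpin/dimer screening or off-target
search in the designer; no polymerase-error or artifact-mutation model
(the effective extension penalty absorbs these); amplitude is normalized,
so weak total amplification is not visible in signal strength; melt-curve
temperatures sit on the 1 M Na⁺ reference scale; heterozygous means
"both peaks present" — no allelic-imbalance modeling.
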