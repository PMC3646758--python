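# Methods

## Growth model and parameter estimation

Simulated OD₆₀₀ curves follow a lag + exponential + deceleration shape. Two
models are available:

* **delayed logistic** (default) — OD(t) = od₀ for t < λ, then the logistic
  OD(t) = OD_max·od₀·e^{µ(t−λ)} / (OD_max + od₀(e^{µ(t−λ)}−1)). The flat lag
  makes lag recovery exact, which keeps the estimator tests sharp.
* **Baranyi** — the smooth adjustment-function model with h₀ = µλ, for users
  who prefer a differentiable lag. Both reduce to the plain logistic at λ=0.

OD noise is multiplicative log-normal (default sd 0.02 on the log scale),
chosen so simulated OD stays positive; flask OD reads at these densities
scatter by a few percent. The simulation grid is 0.5 h.

The estimator is model-free, since batch growth records of this kind are
analysed graphically rather than by nonlinear fitting of a named model:

* **µmax** — the largest least-squares slope of ln OD over all windows of 5
  consecutive points (ties go to the earliest window). Five points at 0.5 h
  spacing bracket the near-linear part of the log-curve; on logistic truth
  the estimate is biased low by roughly od̄/OD_max inside the window, well
  under the 10% recovery tolerance for realistic od₀/OD_max ratios.
* **λ** — the intersection of the max-slope tangent with the baseline
  ln OD level, the mean over the initial plateau (the leading run of points
  with OD ≤ od₀·1.10). The lag is reported absent when the intersection
  falls at or before t = 0 or the plateau is shorter than one sampling
  interval — the convention used for cultures that start growing
  immediately, e.g. on oleic acid.
* **OD max** — the maximum of a centred 3-point rolling median
  (edge-replicated), robust to single-point spikes without flattening
  monotone ends.
* **no growth** — max log-slope below 0.01 h⁻¹ flags the series; lag and
  doubling time are then unset.

Sampling time points are the earliest linear-interpolation crossings of the
smoothed curve through OD_max/5, OD_max/2 and (1−δ)·OD_max with δ = 0.02;
the shave makes the final crossing well defined on asymptotic plateaus.

Synthetic curves built from the published 18-row parameter grid run to
99.5% of OD_max plus a 2 h margin (closed-form logistic saturation time),
so slow oleic-acid growers (µ = 0.18 h⁻¹) actually reach their plateau;
a fixed 30 h window would leave them ~17% short, failing the 2% OD-max
recovery check for reasons that have nothing to do with the estimator.

## Chromatogram model and quantification

Simulated GC-FID traces place one Gaussian per fatty acid at its library
retention time with area k·RF·m (k = 1000 pA·min/µg, a fixed arbitrary
detector constant that cancels in the area-ratio method), σ = 0.04 min on a
100 pts/min grid, plus a linear baseline (10 pA offset, 1 pA/min drift) and
Gaussian noise (2 pA — of the order of the bleed spec of a low-bleed GC
column). The default library spaces C14:0, C16:0, C16:1(n-7), C17:0 (IS),
C18:0, C18:1(n-9) and C18:2(n-6) at 1-minute intervals, so peaks are fully
resolved; retention times closer than 3σ are recorded as overlapping in the
metadata. Co-elution deconvolution and detector saturation are deliberately
not modelled.

Peak detection estimates the baseline by a rolling minimum over 1 min,
smoothed by an equal-width mean, subtracts it, and finds local maxima with
prominence ≥ 50 pA (`scipy.signal.find_peaks`). Integration bounds run from
the apex to the baseline crossing (signal below 0.1% of peak height) or the
shared valley with an adjacent peak; areas are trapezoidal. Flat-topped
peaks are flagged `saturated`, not dropped. Assignment is greedy
globally-nearest matching within ±0.05 min; each library entry captures at
most one peak.

Quantification divides each assigned area by the internal-standard area and
scales by the spiked IS mass (75 µg of C17:0). Response factors default to
1.0 (near-uniform FID response across FAMEs); endogenous C17:0 is assumed
negligible — a documented limitation of spiking an odd-chain FA as IS.
Lipid content counts identified peaks only (configurable through the
library). The aliquot dry weight is cdw_per_od × OD-units harvested; the
default 0.55 mg per OD₆₀₀ unit is typical for *Yarrowia* flask cultures,
and 10 OD units are harvested per aliquot by convention.

## Trajectory classification

With contents c₁, c₂, c₃ at the ⅕, ½ and 1 × OD max points and relative
steps d₁₂, d₂₃ (ε = 0.10 relative, reflecting the ~two-replicate precision
of such measurements):

* rise then fall beyond ε → accumulate-then-mobilize;
* sustained net rise (or flat then rising) → continuous increase;
* net loss without an initial rise → decline;
* otherwise stable.

The rule is scale-invariant. Oleaginy uses a strict 20 %CDW threshold — the
lower bound of the conventional 20–25% band, configurable. The major
compound is taken at the OD-max point; compounds within 1% relative of the
maximum are returned as a tie set, which is how the near-equal C16:0 /
C18:1(n-9) case is represented.

## Reference values and synthetic fill-ins

`reference.py` carries the published growth parameters for the nine type
strains on glucose and oleic acid, and the published lipid-content
landmarks (maxima 67.1, 52.2 and 29.4 %CDW; the 34.4 → 15.2 %CDW decline;
the glucose courses 5.1 → 7.2, 4.0 → 4.5 and 6 → 4.7 %CDW). Trajectory
points not individually published are representative values chosen once to
respect those landmarks and each strain's reported accumulation pattern;
they are labelled synthetic where they appear. Published doubling times are
consistent with ln 2/µmax at 2 d.p. only where the printed µmax did not
lose precision to rounding; exact comparisons are made only on those rows.

The phenotype fixtures are likewise synthetic reconstructions from
strain-level facts: the 3/21/7 universal/unused/variable partition of the
31 non-hydrophobic substrates (universal = glucose, fructose, glycerol;
YAHI uniquely uses trehalose and uniquely fails on lactate and erythritol),
the hydrophobic drop-test constraints (C6 compounds toxic to all strains,
tributyrin/methyl myristate/methyl palmitate universal, the YAAL/YAYA/YALI
substrate gaps) and the tributyrin halo set {YALI, YADE, YAOS, YAPH, YAHO}.
Cells not pinned down by those facts are filled in arbitrarily but fixed;
the partition and halo sets are the fixtures' integrity checks. The
four-level score {growth, weak, none, untested} collapses "delayed, weak or
slow" into one level because drop-test timing is not reproduced, and weak
growth counts as growth in the partition by default. Density-dependent
inhibition (methyl decanoate on minimal medium) is recorded as a free-text
note, not modelled.

## What the synthetic data do and do not show

The generators reproduce the statistical structure the estimators assume:
smooth sigmoid growth, resolved Gaussian peaks with areas linear in mass,
compositions constant across time points within a scenario. Passing tests
therefore demonstrate correctness of the estimators and classification
rules, and robustness at realistic noise — not performance on real
chromatograms with co-elution, drifting retention times or nonlinear
detector response, nor on diauxic or multi-phase growth curves. Replicate
aggregation beyond seeded repeats, inter-strain hypothesis testing and
lipid-class (TAG vs free fatty acid) fractionation are out of scope.

## Problem sizes

The default test suite and the acceptance script run entirely on simulated
data: 61–160-point growth curves, ~900-point chromatograms, 18 scenarios
per full pipeline pass and 20 seeded replicates per recovered %CDW value;
a complete run takes well under a minute on one core.
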