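# nbquant

Quantification of nuclear-body condensates and FRAP exchange kinetics
from fluorescence time-lapse microscopy, with a synthetic-microscopy
generator for ground-truth validation.

Membraneless nuclear condensates such as PML nuclear bodies and nucleoli
can harden from a liquid-like to a solid-like state when misfolded
proteins accumulate in them. Two imaging read-outs diagnose that
transition: (1) **FRAP** — bleach a small region inside the structure and
measure how much fluorescence returns and how fast, separating fast,
slow and immobile molecular populations; (2) **high-content
quantification** — segment the bodies, score how strongly a protein of
interest is enriched inside each body relative to the surrounding
nucleoplasm, and count foci per nucleus. This package implements both
pipelines end to end for people who have the raw TIFF stacks and want an
open, scriptable, tested alternative to plug-in-based analysis.

## The computations at the core

**Double normalization.** With per-frame ROI means and the camera offset
measured by a background ROI,

```
N(t) = [(I_bleach(t) − I_bg(t)) / (I_bleach(t0) − I_bg(t0))]
     / [(I_total(t)  − I_bg(t)) / (I_total(t0)  − I_bg(t0))]
```

which cancels global acquisition photobleaching and pins the pre-bleach
level at 1 (t0 statistics are means over the pre-bleach frames).

**Recovery fit.** `N(t) = floor + A_f(1 − e^(−k_f t)) + A_s(1 − e^(−k_s t))`,
single- vs double-exponential selected by AICc; mobile fraction
normalized for bleach depth, `(plateau − floor)/(1 − floor)`; populations
`immobile = 1 − mobile`, `fast/slow = mobile · A_f,s/(A_f + A_s)`.

**Enrichment ratio.** Mean intensity inside a segmented body divided by
the mean in a surrounding nucleoplasmic annulus (3 px ring, 1 px guard
gap, offset-subtracted); a body is enriched when the ratio exceeds 1.5.
Foci counts per nucleus are binned into `0 / 1–2 / ≥3`.

**Statistics.** One-way ANOVA with Holm-adjusted pairwise Student's
t-tests, or a two-tailed pooled t-test for two groups.

Drift is corrected before trace extraction by subpixel phase correlation
against an aligned pre-bleach reference. See `docs/methods.md` for the
models, assumptions and numerical choices.

## Worked example

```python
import numpy as np
from nbquant import simgen, registration, frap, bodies

# --- FRAP: simulate, register, normalize, fit -------------------------
fp = simgen.frap_field_params(seed=42)                   # 1 nucleus, SNR 20
pp = simgen.FrapSimParams(frac_fast=0.5, frac_slow=0.3,  # truth: mobile 0.8
                          frac_immobile=0.2, seed=42)
movie = simgen.make_frap_movie(fp, pp)

stack, traj = registration.register_stack(movie.stack, n_prebleach=movie.n_prebleach)
trace = frap.extract_traces(stack, movie.rois, movie.n_prebleach)
fit = frap.fit_recovery(frap.double_normalize(trace), model="auto")
fast, slow, imm = frap.classify_populations(fit)
print(f"model:            {fit.model}")
print(f"mobile fraction:  {fit.mobile_fraction:.3f}   (truth 0.800)")
print(f"populations:      fast {fast:.3f}, slow {slow:.3f}, immobile {imm:.3f}")
print(f"rates:            k_fast {fit.k_fast:.3f}/s, k_slow {fit.k_slow:.4f}/s")

# --- bodies: segment, score enrichment, count foci --------------------
field = simgen.make_field(simgen.SimFieldParams(cargo_enrichment=2.0, seed=42))
nuclei = bodies.segment_nuclei(field.channels["nuclei"])
found = bodies.segment_bodies(field.channels["bodies"], nuclei)
enr = bodies.enrichment(found, nuclei, field.channels["cargo"], camera_offset=100.0)
counts = bodies.count_foci(found, nuclei)
labels, pct = bodies.categorize_counts(list(counts.values()))
ratios = [r.ratio for r in enr.records if r.valid]
print(f"nuclei: {nuclei.n_labels}, bodies: {found.n_labels} (truth {len(field.truth.bodies)})")
print(f"median enrichment ratio: {np.median(ratios):.2f}  (truth 2.00)")
print(f"fraction enriched (>1.5): {enr.fraction_enriched:.2f}")
print(f"foci categories: {pct}")
```

Output:

```
model:            double-exp
mobile fraction:  0.803   (truth 0.800)
populations:      fast 0.507, slow 0.296, immobile 0.197
rates:            k_fast 0.207/s, k_slow 0.0168/s
nuclei: 8, bodies: 31 (truth 31)
median enrichment ratio: 2.00  (truth 2.00)
fraction enriched (>1.5): 1.00
foci categories: {'0': 0.0, '1-2': 0.0, '>=3': 100.0}
```

The fitted mobile fraction (0.803) and population split (0.507, 0.296,
0.197) recover the planted truth (0.8; 0.5/0.3/0.2); the fitted rates
correspond to the planted 5 s and 60 s time constants. On the field, all
31 planted bodies are detected and the planted 2.0× cargo enrichment is
recovered exactly on the median.

The same pipelines are available from the shell:

```sh
nbquant simulate frap --seed 1 --out movie/
nbquant frap-analyze --stack movie/stack.tif --rois movie/rois.json --prebleach 5
nbquant simulate field --seed 1 --out field/
nbquant bodies-quantify --field-dir field/ --out quant/
nbquant stats-compare --table measurements.csv
```

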