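# screenbounds

Analytic limits on recall rate (RR) and expected protocol duration (EPD)
for an **adaptive two-stage screening policy**: everyone starts on an
abbreviated exam, and an AI reader decides on the spot whether to continue
with the full exam. People flagged by the radiologist but not by the AI
must be recalled for a second, full-protocol visit.

Because only the marginal performance of the two readers (sensitivity /
specificity) is known — not their joint behaviour — the adaptive metrics
are not single numbers. This package computes **sharp lower/upper limits**
by applying Fréchet–Hoeffding bounds to the readers' flag overlap within
each disease stratum, and provides:

- **`screenbounds.model`** — confusion-rate algebra, overlap bounds, the
  three strategies (abbreviated-only, full-only, adaptive best/worst case);
- **`screenbounds.sweeps`** — one-at-a-time parameter sweeps, piecewise
  linear breakpoint detection with bisection refinement, the
  "likely band" built from an agreement-accuracy interval, percent
  reduction vs. the full protocol;
- **`screenbounds.cohort`** — a seeded Monte-Carlo / expected-count cohort
  simulator that generates per-person (disease, radiologist flag, AI flag)
  records under controllable couplings and validates the analytic bounds
  empirically;
- **`screenbounds.config` / `io` / `figures` / `cli`** — YAML
  configuration with defaults, CSV/JSON serialization, figure rendering
  and a command-line interface.

Default parameters: radiologist 90%/92% (sensitivity/specificity) on the
abbreviated protocol, 92%/95% on the full protocol (carried but unused by
the limit formulas), durations 262 s / 776 s, malignancy prevalence 1.46%,
AI operating point free (0.80/0.80 when not swept).

## Quick start (library)

```python
import screenbounds as sb

cfg = sb.default_config()
m = sb.adaptive_bounds(cfg.rad_abbr, cfg.ai, cfg.cohort(), cfg.timing())
print(m.rr)    # Bounds(lower=0.00146, upper=0.081752)
print(m.epd)   # Bounds(lower=370.4356, upper=432.742192)  [seconds]

result = sb.run_sweep(sb.SweepSpec("ai_sensitivity", tuple(sb.default_grid("ai_sensitivity"))))
print(sb.detect_breakpoints(result, "rr_adaptive_lower"))  # [0.9]
```

## Command line

Every subcommand accepts `--config cfg.yaml` (missing keys take the
defaults above; rates may be written as fractions or percent strings like
`"92%"`) and `-o OUTDIR`, and echoes the effective configuration into the
output directory.

```bash
screenbounds evaluate -o out/                     # all three strategies at one point
screenbounds sweep --parameter ai_specificity -o out/   # sweep + breakpoints
screenbounds band -o out/                         # likely band along the sweep
screenbounds simulate --size 1000000 --coupling max_overlap -o out/
screenbounds validate -o out/                     # oracle vs analytic bounds
screenbounds figures --parameter ai_specificity -o out/
```

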