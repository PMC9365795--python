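# th1select

A Python toolkit for the computational chain behind multiantigen cancer-vaccine
development: selecting candidate antigens from differential-expression
summaries, calling antigen-specific T-cell responses from ELISPOT spot counts,
classifying peptide epitopes as Th1- or Th2-selective, and quantifying
preclinical vaccine efficacy from caliper tumor measurements. A seeded
synthetic-data generator emulates every input, so the whole pipeline runs and
is testable without any external data.

It is written for tumor immunologists and biostatisticians who have per-gene
expression summaries, plate-level ELISPOT counts, or mouse tumor-challenge
measurements and want the downstream selection and efficacy statistics to be
reproducible and scriptable.

## The statistics at the core

**Antigen funnel.** A gene is a candidate when it is upregulated versus normal
tissue in both a low-grade (Gleason ≤ 6) and a high-grade (Gleason ≥ 8)
stratum — log2 fold change > 1 and FDR < 0.05, both strict — and then survives
curated annotation filters (evidence of expression in prostatic
intraepithelial neoplasia; protein detected in the target tumor line). An
include-list admits externally chosen antigens past the expression filters.

**ELISPOT response calling.** For each donor × epitope × cytokine unit with
replicate experimental and no-antigen control wells, the corrected spots per
well is

```
CSPW = mean(experimental wells) − mean(control wells)
```

and a donor is a positive responder when an unpaired two-tailed test on the
replicates gives p < 0.05 *and* CSPW > 0. A cohort reduces to incidence (% of
donors positive) and magnitude (mean CSPW over responders).

**Th1/Th2 selectivity.** Each epitope's paired IFN-γ and IL-10 summaries give

```
ratio = (IFN-γ incidence × magnitude) / (IL-10 incidence × magnitude)
```

ratio > 4 with IL-10 incidence ≤ 10% ⇒ Th1-selective; ratio < 1 ⇒
Th2-selective; between ⇒ mixed; both products zero ⇒ non-reactive.

**Efficacy.** Caliper volume = length × width × height × 0.5236 (mm³); percent
inhibition = 100 × (1 − treated mean / control mean); two-way ANOVA
(arm × day) with Dunnett contrasts against the adjuvant control; survival via
the 2000 mm³ termination rule (linear interpolation between caliper days) with
administrative censoring at day 115, Kaplan–Meier estimation, Fisher's exact
test, and a noncentral-t group-size calculator.

## Worked example

```python
from th1select import elispot, selectivity, synth

wells = synth.gen_elispot_cohort(
    n_donors=10, profiles=synth.default_epitope_panel(), seed=3)
responses = elispot.call_cohort(elispot.wells_to_assays(wells))
summaries = elispot.cohort_summaries(responses)
print(selectivity.calls_frame(selectivity.classify_panel(summaries)))
```

prints

```
   epitope  ifng_incidence  ifng_magnitude  il10_incidence  il10_magnitude              ratio         label
AMACR-p200            60.0       24.166667            50.0        22.05000 1.3151927437641724         MIXED
   HIV-p52             0.0        0.000000             0.0         0.00000                nan  NON_REACTIVE
  HPN-p393            90.0       35.611111             0.0         0.00000                inf TH1_SELECTIVE
   MYC-p30             0.0        0.000000            80.0        37.78125                0.0 TH2_SELECTIVE
 PSMA-p466            60.0       36.500000             0.0         0.00000                inf TH1_SELECTIVE
```

The two epitopes with strong IFN-γ products and no IL-10 response are the
vaccine candidates; the IL-10-only epitope would be edited out; the inert
control peptide is non-reactive. The `examples/` directory has one short
script per capability (funnel, ELISPOT calls, selectivity, tumor efficacy,
full pipeline), and the `th1select` command exposes the same stages from the
shell (`th1select run --config cfg.json`).

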