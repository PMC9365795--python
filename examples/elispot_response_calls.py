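"""Call ELISPOT responses and summarize a donor cohort.

Simulates a 10-donor cohort for one IFN-γ-dominant epitope (4 replicate
experimental wells vs 4 no-antigen control wells per assay), calls each
donor's response, and reduces the calls to cohort incidence and magnitude.
"""

from th1select import elispot, synth

wells = synth.gen_elispot_cohort(
    n_donors=10, profiles=[synth.strong_th1_profile("PSMA-p466")], seed=5)
assays = elispot.wells_to_assays(wells)

responses = elispot.call_cohort(assays, alpha=0.05)
for r in responses[:4]:
    print(f"{r.donor_id} {r.epitope_id} {r.cytokine.value:4s} "
          f"CSPW={r.cspw:6.2f}  p={r.p_value:.4f}  positive={r.positive}")
print("...")

for s in elispot.cohort_summaries(responses):
    print(f"{s.epitope_id} {s.cytokine.value:4s} incidence={s.incidence:5.1f}% "
          f"magnitude={s.magnitude:.1f} spots/well over {s.n_donors} donors")

# CSPW is mean experimental minus mean control spots; a donor is positive
# when the replicate difference is significant (p < 0.05) AND CSPW > 0.
# Incidence is the percent of positive donors; magnitude averages CSPW over
# the responders only.
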