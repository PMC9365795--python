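"""Classify a panel of epitopes as Th1-selective, Th2-selective or mixed.

Simulates a five-epitope panel (two IFN-γ-dominant, one mixed, one
IL-10-only, one inert), runs the full call → summarize → classify chain,
and prints the selectivity ratio and label for each epitope.
"""

from th1select import elispot, selectivity, synth

wells = synth.gen_elispot_cohort(
    n_donors=10, profiles=synth.default_epitope_panel(), seed=3)
responses = elispot.call_cohort(elispot.wells_to_assays(wells))
summaries = elispot.cohort_summaries(responses)
calls = selectivity.classify_panel(summaries)

print(selectivity.calls_frame(calls).to_string(index=False))

# The ratio is (IFN-γ incidence × magnitude) / (IL-10 incidence × magnitude):
# > 4 with IL-10 incidence <= 10% means Th1-selective (a vaccine candidate),
# < 1 means Th2-selective (edited out of a vaccine), in between is mixed;
# "inf" marks epitopes with no IL-10 product at all and "nan" inert ones.
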