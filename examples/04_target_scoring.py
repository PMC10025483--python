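"""Duplex alignment and compliance scoring for miR172b-5p.

Plants a perfect reverse-complement site for the miR172b-5p sequence in a
synthetic transcript, aligns, renders the duplex, and shows how degradome
evidence moves the compliance score (0 best, 18 worst).
"""

import numpy as np

from mirstress import TranscriptProfile, align_duplex, compliance_score, render_alignment, score_hit
from mirstress.simulate import MIR172B_5P, reverse_complement

site = reverse_complement(MIR172B_5P)
transcript = "GATTACAGATTACAGATT" + site + "CAGATTACAGATTACAGATTA"

hits = align_duplex(MIR172B_5P, transcript, "hvu-miR172b-5p", "TPS-like")
best = hits[0]
print(render_alignment(best, MIR172B_5P, transcript))
print(f"penalty {best.penalty}, predicted cleavage at position {best.predicted_cleavage}\n")

# degradome support: a rank-1 peak at the predicted site -> compliance 0
raw = np.zeros(len(transcript), dtype=int)
raw[best.predicted_cleavage - 1] = 30
raw[5] = 4
profile = TranscriptProfile("TPS-like", len(transcript), "ak", raw)
supported = score_hit(best, profile, library_total=1000)
print(f"with a rank-{supported.site_rank} degradome peak: compliance {supported.compliance}")
print(f"without degradome support:                 compliance {score_hit(best, None).compliance}")
print(f"worst admissible case:                     compliance {compliance_score(7.5, None, False)}")
# Lower is better: perfect pairing + rank-1 cleavage evidence scores 0;
# a capped-penalty duplex with no degradome signal scores the maximum 18.
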