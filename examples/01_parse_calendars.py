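"""Parse raw DHS-style calendar strings into 59-month state sequences.

Builds three tiny hand-written records (the leftmost calendar column is
the interview month), recodes them with the default DHS-7 code map, and
prints the resulting fixed-length state sequences.
"""

from calseg import CalendarRecord, build_sequences, filter_eligible

records = [
    # five years of non-use
    CalendarRecord("quiet", "0" * 80, interview_cmc=1404, birth_cmc=1050,
                   weight=1.0, psu=1, stratum=1),
    # injectable use, then a pregnancy ending in a birth (B), then non-use
    CalendarRecord("recent_mother", "000000BPPPPPPPP333333" + "0" * 59,
                   interview_cmc=1404, birth_cmc=1080,
                   weight=1.2, psu=1, stratum=1),
    # aged 50 at the window start: filtered out
    CalendarRecord("too_old", "0" * 80, interview_cmc=1404, birth_cmc=746,
                   weight=0.9, psu=2, stratum=1),
]

eligible, report = filter_eligible(records)
print(f"eligibility: kept {report['kept']}, dropped {report['dropped']}")

seqs, excluded = build_sequences(eligible)
for s in seqs:
    print(f"{s.case_id:>14}: {s.letters}")

# Each line is 59 letters, month 1 (earliest) first:
# N = no use, S = short-term modern, L = long-acting/permanent,
# T = traditional, P = pregnancy/birth/termination.
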