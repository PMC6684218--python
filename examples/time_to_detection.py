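"""Time-to-detection: forum first-report dates vs literature dates.

Builds the cumulative post-count curve for a drug-ADR pair and computes
the lead time in whole months between the first forum report and the
first literature report.
"""

from datetime import date

from adrsignal.stats import PairRecord
from adrsignal.timeline import (
    LiteratureEvent,
    cumulative_series,
    first_report_date,
    lead_table,
)

records = [
    PairRecord("examplinib", "blistering", f"u{i}", f"p{i}", d)
    for i, d in enumerate(
        [
            date(2014, 10, 12),
            date(2014, 11, 3),
            date(2014, 11, 3),
            date(2015, 2, 20),
            date(2015, 6, 1),
            date(2015, 9, 14),
        ]
    )
]
events = [
    LiteratureEvent("examplinib", "blistering", date(2015, 7, 1), "first case report",
                    "case_report"),
    LiteratureEvent("examplinib", "blistering", date(2016, 5, 1), "three-case series",
                    "case_series"),
]

first = first_report_date(records, "examplinib", "blistering")
print(f"first forum report: {first}")
series = cumulative_series(records, "examplinib", "blistering")
print("cumulative curve (date -> running post count):")
for d, c in series.points:
    print(f"  {d}  {c}")
[row] = lead_table(records, events)
print(f"first literature report: {row['first_literature'].strftime('%Y-%m')} "
      f"({row['citation']})")
print(f"lead time: {row['lead_months']} months")
print("-> a positive lead means forum users described the reaction before")
print("   the first published report; the earliest literature event counts.")
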