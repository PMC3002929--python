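#!/usr/bin/env python
"""TP53 mutation-class statistics on the packaged tumor table.

Parses every mutation string, classifies complex/truncating mutations and
hotspot missense changes, summarizes the four tumor groups, and runs
two-tailed Fisher exact tests on the key contrasts. Outputs go to
results/tp53/.
"""

from pathlib import Path

import pandas as pd

from cghcompare import tp53

OUT = Path(__file__).resolve().parent.parent / "results" / "tp53"

CONTRASTS = [
    ("BLBC", "luminal-H", "mutated"),
    ("BRCA1", "luminal-J", "mutated"),
    ("BLBC", "luminal-H", "complex"),
    ("BRCA1", "luminal-J", "complex"),
    ("BLBC", "luminal-H", "hotspot"),
    ("BRCA1", "luminal-J", "hotspot"),
]


def main() -> None:
    records = tp53.load_table1_records()
    groups = ("BRCA1", "BLBC", "luminal-H", "luminal-J")
    summaries = {g: tp53.group_summary(records, g) for g in groups}

    OUT.mkdir(parents=True, exist_ok=True)
    summary_df = pd.DataFrame([vars(s) for s in summaries.values()])
    summary_df.to_csv(OUT / "group_summary.tsv", sep="\t", index=False)
    print(summary_df.to_string(index=False))

    rows = []
    for ga, gb, feature in CONTRASTS:
        table, p = tp53.compare_groups(summaries[ga], summaries[gb], feature)
        rows.append({
            "group_a": ga, "group_b": gb, "feature": feature,
            "a_pos": table[0][0], "a_neg": table[0][1],
            "b_pos": table[1][0], "b_neg": table[1][1],
            "p_two_tailed": p,
        })
        verdict = "significant" if p < 0.01 else "ns"
        print(f"{feature:>10} {ga} vs {gb}: "
              f"{table[0][0]}/{sum(table[0])} vs {table[1][0]}/{sum(table[1])} "
              f"p = {p:.1e} ({verdict})")
    pd.DataFrame(rows).to_csv(OUT / "fisher_tests.tsv", sep="\t", index=False)
    print(f"wrote {OUT}/{{group_summary.tsv,fisher_tests.tsv}}")


if __name__ == "__main__":
    main()
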