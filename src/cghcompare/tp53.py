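"""TP53 mutation-string parsing, classification and exact group statistics.

The mutation nomenclature handled here is the free-text dialect of clinical
tumor-sequencing tables: protein substitutions ("R175H", "R213X"), nucleotide
insertions/deletions with a codon anchor ("239 insT", "110delC",
"255_256delTCA"), codon-range deletions ("del 155-156", "155_156del") and
splice-site notations ("IVS5-2 A > C (splice)", "224 splice G > A").

"Complex" mutations are the typically protein-truncating classes: frameshift,
splice and nonsense mutations plus in-frame insertions/deletions. Hotspot
calls use the 29 recurrently mutated TP53 codons of Walker et al.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


class MutationKind(str, Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT_INS = "frameshift_ins"
    FRAMESHIFT_DEL = "frameshift_del"
    INFRAME_INS = "inframe_ins"
    INFRAME_DEL = "inframe_del"
    SPLICE = "splice"
    WILD_TYPE = "wild_type"
    NOT_SEQUENCED = "not_sequenced"


#: Truncating / complex classes.
COMPLEX_KINDS = frozenset(
    {
        MutationKind.NONSENSE,
        MutationKind.FRAMESHIFT_INS,
        MutationKind.FRAMESHIFT_DEL,
        MutationKind.INFRAME_INS,
        MutationKind.INFRAME_DEL,
        MutationKind.SPLICE,
    }
)

#: The 29 most common TP53 hotspot codons (Walker et al.), as (ref_aa, codon).
HOTSPOTS: frozenset[tuple[str, int]] = frozenset(
    {
        ("K", 132), ("C", 135), ("P", 151), ("V", 157), ("R", 158),
        ("Y", 163), ("V", 173), ("R", 175), ("C", 176), ("H", 179),
        ("H", 193), ("Y", 205), ("Y", 220), ("Y", 234), ("M", 237),
        ("C", 238), ("S", 241), ("C", 242), ("G", 245), ("M", 246),
        ("R", 248), ("R", 249), ("G", 266), ("R", 273), ("P", 278),
        ("R", 280), ("D", 281), ("R", 282), ("E", 285),
    }
)
assert len(HOTSPOTS) == 29


@dataclass(frozen=True)
class MutationRecord:
    """One parsed TP53 mutation (or a wild-type / not-sequenced sample row)."""

    sample_id: str
    group: str
    raw: str
    kind: MutationKind
    codon: int | None = None
    ref_aa: str | None = None
    alt_aa: str | None = None
    predicted_deleterious: bool | None = None  # None = unknown
    abundance_fraction: float | None = None  # None = unknown

    def format(self) -> str:
        """Return the token this record parses back from (parse-stable)."""
        return self.raw


_RE_SUBST = re.compile(r"^([A-Z])\s*(\d+)\s*([A-Z])$")
_RE_INDEL = re.compile(r"^(\d+)(?:_(\d+))?\s*(del|ins)\s*([ACGT]+)$", re.IGNORECASE)
_RE_RANGE_DEL = re.compile(r"^del\s*(\d+)(?:\s*-\s*(\d+))?$", re.IGNORECASE)
_RE_CODON_RANGE_DEL = re.compile(r"^(\d+)_(\d+)\s*del$", re.IGNORECASE)


def _parse_token(token: str) -> dict:
    """Classify one mutation token; returns kind/codon/ref/alt fields."""
    tok = token.strip()
    low = tok.lower()
    if low in ("wild type", "wildtype", "wild-type", "wt"):
        return {"kind": MutationKind.WILD_TYPE}
    if tok in ("NA", "N/A", "") or low == "not sequenced":
        return {"kind": MutationKind.NOT_SEQUENCED}
    if "splice" in low or "ivs" in low:
        return {"kind": MutationKind.SPLICE}
    m = _RE_SUBST.match(tok)
    if m:
        ref, codon, alt = m.group(1), int(m.group(2)), m.group(3)
        kind = MutationKind.NONSENSE if alt == "X" else MutationKind.MISSENSE
        return {"kind": kind, "codon": codon, "ref_aa": ref, "alt_aa": alt}
    m = _RE_INDEL.match(tok)
    if m:
        codon = int(m.group(1))
        op = m.group(3).lower()
        payload = m.group(4)
        frameshift = len(payload) % 3 != 0
        if op == "ins":
            kind = MutationKind.FRAMESHIFT_INS if frameshift else MutationKind.INFRAME_INS
        else:
            kind = MutationKind.FRAMESHIFT_DEL if frameshift else MutationKind.INFRAME_DEL
        return {"kind": kind, "codon": codon}
    m = _RE_RANGE_DEL.match(tok) or _RE_CODON_RANGE_DEL.match(tok)
    if m:
        return {"kind": MutationKind.INFRAME_DEL, "codon": int(m.group(1))}
    raise ValueError(f"unparseable TP53 mutation token: {token!r}")


def parse_mutation(
    raw: str,
    sample_id: str = "",
    group: str = "",
    predicted_deleterious: bool | None = None,
    abundance_fraction: float | None = None,
) -> list[MutationRecord]:
    """Parse a mutation cell; comma-separated lists yield multiple records."""
    if not raw or not raw.strip():
        raise ValueError("empty mutation string")
    records = []
    for token in raw.split(","):
        fields = _parse_token(token)
        records.append(
            MutationRecord(
                sample_id=sample_id,
                group=group,
                raw=token.strip(),
                predicted_deleterious=predicted_deleterious,
                abundance_fraction=abundance_fraction,
                **fields,
            )
        )
    return records


def classify(
    record: MutationRecord, hotspots: frozenset[tuple[str, int]] = HOTSPOTS
) -> dict[str, bool]:
    """Flags for one record: is_complex, is_missense, is_hotspot."""
    is_complex = record.kind in COMPLEX_KINDS
    is_missense = record.kind is MutationKind.MISSENSE
    is_hotspot = (
        is_missense
        and record.ref_aa is not None
        and record.codon is not None
        and (record.ref_aa, record.codon) in hotspots
    )
    return {"is_complex": is_complex, "is_missense": is_missense,
            "is_hotspot": is_hotspot}


@dataclass(frozen=True)
class GroupSummary:
    group: str
    n_sequenced: int
    n_mutated: int
    n_complex: int
    n_deleterious_missense: int
    n_hotspot: int

    def feature_count(self, feature: str) -> int:
        try:
            return {
                "mutated": self.n_mutated,
                "complex": self.n_complex,
                "deleterious_missense": self.n_deleterious_missense,
                "hotspot": self.n_hotspot,
            }[feature]
        except KeyError:
            raise ValueError(f"unknown feature {feature!r}") from None


def group_summary(
    records: Iterable[MutationRecord], group: str, abundance_min: float = 0.25
) -> GroupSummary:
    """Tumor-level counts for one group (tumors, never mutations).

    Tumors whose only record is not_sequenced are excluded. A mutation counts
    only if its estimated abundance exceeds ``abundance_min`` or is unknown.
    """
    by_sample: dict[str, list[MutationRecord]] = {}
    seen_groups = set()
    for r in records:
        seen_groups.add(r.group)
        if r.group == group:
            by_sample.setdefault(r.sample_id, []).append(r)
    if not by_sample:
        raise ValueError(
            f"unknown group {group!r}; groups present: {sorted(seen_groups)}"
        )
    n_seq = n_mut = n_complex = n_del_mis = n_hot = 0
    for recs in by_sample.values():
        informative = [r for r in recs if r.kind is not MutationKind.NOT_SEQUENCED]
        if not informative:
            continue
        n_seq += 1
        passing = [
            r
            for r in informative
            if r.kind is not MutationKind.WILD_TYPE
            and (r.abundance_fraction is None or r.abundance_fraction > abundance_min)
        ]
        if not passing:
            continue
        n_mut += 1
        flags = [classify(r) for r in passing]
        if any(f["is_complex"] for f in flags):
            n_complex += 1
        if any(
            f["is_missense"] and r.predicted_deleterious is True
            for f, r in zip(flags, passing)
        ):
            n_del_mis += 1
        if any(f["is_hotspot"] for f in flags):
            n_hot += 1
    return GroupSummary(group, n_seq, n_mut, n_complex, n_del_mis, n_hot)


def fisher_exact_two_tailed(table: Sequence[Sequence[int]]) -> float:
    """Two-tailed Fisher exact p (min-likelihood convention).

    Sums hypergeometric probabilities of all tables with the observed margins
    whose probability does not exceed the observed table's (within 1e-12).
    A table with a zero margin carries no information: p = 1.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of non-negative counts")
    if t.sum() < 1:
        raise ValueError("empty table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return 1.0
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def compare_groups(
    summary_a: GroupSummary, summary_b: GroupSummary, feature: str
) -> tuple[list[list[int]], float]:
    """2x2 table (feature-positive vs negative x group) and its Fisher p."""
    a_pos = summary_a.feature_count(feature)
    b_pos = summary_b.feature_count(feature)
    table = [
        [a_pos, summary_a.n_sequenced - a_pos],
        [b_pos, summary_b.n_sequenced - b_pos],
    ]
    return table, fisher_exact_two_tailed(table)


# --- tabular I/O ------------------------------------------------------------

_BOOL = {"true": True, "false": False}


def records_from_table(table: pd.DataFrame) -> list[MutationRecord]:
    """Parse a mutation table (sample_id, group, raw, predicted_deleterious,
    abundance) into records; one table row may yield several records."""
    records: list[MutationRecord] = []
    for _, row in table.iterrows():
        flag = _BOOL.get(str(row.get("predicted_deleterious", "NA")).lower())
        ab_raw = str(row.get("abundance", "NA"))
        abundance = None if ab_raw in ("NA", "nan", "") else float(ab_raw)
        records.extend(
            parse_mutation(
                str(row["raw"]),
                sample_id=str(row["sample_id"]),
                group=str(row["group"]),
                predicted_deleterious=flag,
                abundance_fraction=abundance,
            )
        )
    return records


def read_mutation_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def load_table1() -> pd.DataFrame:
    """The packaged tumor-characteristics mutation fixture.

    Columns: sample_id, group, raw, predicted_deleterious, abundance,
    complex_flag, hotspot_flag. The complex/hotspot flags are the table's
    printed per-sample annotations, stored for cross-checks; hotspot calls in
    this package always come from the 29-codon list, which disagrees with the
    printed flag for a few rows.
    """
    ref = resources.files("cghcompare.data") / "table1_mutations.tsv"
    with resources.as_file(ref) as p:
        return read_mutation_table(p)


def load_table1_records() -> list[MutationRecord]:
    return records_from_table(load_table1())
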