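"""Motif-based mtDNA haplogroup assignment from rule tables.

Haplogroups are named clades of the mtDNA phylogeny defined by diagnostic
variant motifs (Phylotree-style).  Rule tables are *data*, not code: the
nomenclature is versioned, so the caller supplies a table (TSV) mapping a
haplogroup label to its required and forbidden variants.  A small
rule-based matcher stands in for fragment-aware classifiers: the rule
with the fewest missing required variants wins, a forbidden-variant hit
disqualifies a rule outright (back-mutations of former diagnostic sites
are real in this system), and ties go to the least-derived label.

The haplogroup-P machinery used for phylogeographic work is explicit:
``is_P1`` implements the minimal HVS pattern [73G 263G 315.1C] 16357C,
where the bracketed variants are only evaluated when the sample's reading
frame covers them (HVS-I-only data can still be called), and
``classify_P_category`` partitions P carriers into P1* / P1d1 / PxP1.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import pandas as pd

from .codec import (
    FrameError,
    Haplotype,
    ReadingFrame,
    Variant,
    insertion,
    parse_haplotype,
    substitution,
)

P1_REQUIRED = substitution(16357, "C")
P1_BRACKETED = (substitution(73, "G"), substitution(263, "G"), insertion(315, 1, "C"))


@dataclass(frozen=True)
class MotifRule:
    haplogroup: str
    required: frozenset[Variant]
    forbidden: frozenset[Variant] = frozenset()
    min_frame: ReadingFrame | None = None
    parent: str | None = None

    def __post_init__(self) -> None:
        if self.required & self.forbidden:
            raise ValueError(
                f"rule {self.haplogroup}: required and forbidden sets overlap"
            )


@dataclass(frozen=True)
class Assignment:
    haplogroup: str
    matched: int
    mismatches: int
    ambiguous: bool


def assign_haplogroup(h: Haplotype, rules: list[MotifRule]) -> Assignment:
    """Best-matching rule: fewest missing required variants after frame
    restriction; forbidden hit disqualifies; ties -> least-derived label,
    flagged ambiguous."""
    if not rules:
        raise ValueError("empty rule table")
    hv = set(h.variants)
    scored: list[tuple[int, int, int, str, MotifRule, int]] = []
    for rule in rules:
        if any(f in hv for f in rule.forbidden):
            continue
        covered = [v for v in rule.required if h.frame.contains(v.position)]
        matched = sum(1 for v in covered if v in hv)
        mism = len(covered) - matched
        scored.append((mism, -matched, len(rule.required), rule.haplogroup, rule, matched))
    if not scored:
        return Assignment("unassigned", 0, 0, True)
    scored.sort(key=lambda t: t[:4])
    best = scored[0]
    tie = len(scored) > 1 and scored[1][:2] == best[:2]
    return Assignment(best[4].haplogroup, best[5], best[0], tie)


def is_P1(h: Haplotype) -> bool:
    """Minimal haplogroup-P1 pattern [73G 263G 315.1C] 16357C.

    True iff the transition 16357C is present and each bracketed variant
    is present wherever its np is covered by the sample's frame.  Raises
    FrameError if np 16357 is not covered at all.
    """
    if not h.frame.contains(16357):
        raise FrameError("frame does not cover np 16357; P1 status undecidable")
    hv = set(h.variants)
    if P1_REQUIRED not in hv:
        return False
    return all(v in hv for v in P1_BRACKETED if h.frame.contains(v.position))


def classify_P_category(
    h: Haplotype,
    p1d1_motif: frozenset[Variant],
    p_rule: MotifRule,
) -> str:
    """Partition P carriers into 'P1d1', 'P1*', 'PxP1'; others are 'not-P'.

    `p_rule` defines haplogroup-P membership; `p1d1_motif` is the HVS-I
    motif distinguishing P1d1 within P1 (config-supplied, nomenclature-
    version dependent).
    """
    if not p1d1_motif:
        raise ValueError("P1d1 motif must be supplied (config)")
    hv = set(h.variants)
    covered_req = [v for v in p_rule.required if h.frame.contains(v.position)]
    is_p = bool(covered_req) and all(v in hv for v in covered_req) and not any(
        f in hv for f in p_rule.forbidden
    )
    p1 = is_P1(h)
    if p1:
        return "P1d1" if all(v in hv for v in p1d1_motif) else "P1*"
    if is_p:
        return "PxP1"
    return "not-P"


def haplogroup_frequency_table(pops, rules: list[MotifRule]) -> pd.DataFrame:
    """Per-population haplogroup counts and percentages (long layout).

    Returns a DataFrame with columns Population, Haplogroup, n, pct;
    within each population the counts sum to the sample size and the
    percentages to 100 up to rounding.
    """
    records = []
    for pop in pops:
        counts: dict[str, int] = {}
        for h in pop.haplotypes:
            label = assign_haplogroup(h, rules).haplogroup
            counts[label] = counts.get(label, 0) + 1
        n = len(pop.haplotypes)
        for label in sorted(counts):
            records.append(
                {
                    "Population": pop.name,
                    "Haplogroup": label,
                    "n": counts[label],
                    "pct": round(100.0 * counts[label] / n, 1),
                }
            )
    return pd.DataFrame.from_records(
        records, columns=["Population", "Haplogroup", "n", "pct"]
    )


# ---------------------------------------------------------------------------
# Rule-table TSV I/O: Haplogroup, Parent, Required, Forbidden, MinFrame


def _parse_variant_field(text: str, frame: ReadingFrame) -> frozenset[Variant]:
    text = text.strip()
    if not text or text == ".":
        return frozenset()
    return frozenset(parse_haplotype(text, frame).variants)


def load_rules(path) -> list[MotifRule]:
    full = ReadingFrame(((1, 16569),))
    rules = []
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh, delimiter="\t")
                if r and not r[0].startswith("#")]
    header = rows[0]
    col = {name: header.index(name) for name in header}
    for row in rows[1:]:
        frame_text = row[col["MinFrame"]].strip() if "MinFrame" in col else ""
        min_frame = ReadingFrame.parse(frame_text) if frame_text and frame_text != "." else None
        parent = row[col["Parent"]].strip() if "Parent" in col else ""
        rules.append(
            MotifRule(
                haplogroup=row[col["Haplogroup"]].strip(),
                required=_parse_variant_field(row[col["Required"]], full),
                forbidden=_parse_variant_field(row[col["Forbidden"]], full)
                if "Forbidden" in col else frozenset(),
                min_frame=min_frame,
                parent=parent or None,
            )
        )
    labels = [r.haplogroup for r in rules]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate haplogroup labels in rule table")
    return rules


def write_rules(rules: list[MotifRule], path) -> None:
    def fmt(vs: frozenset[Variant]) -> str:
        return " ".join(v.token for v in sorted(vs, key=lambda v: v.site)) or "."

    with open(path, "w") as fh:
        fh.write("Haplogroup\tParent\tRequired\tForbidden\tMinFrame\n")
        for r in rules:
            fh.write(
                f"{r.haplogroup}\t{r.parent or '.'}\t{fmt(r.required)}\t"
                f"{fmt(r.forbidden)}\t{r.min_frame if r.min_frame else '.'}\n"
            )
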