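"""Parse, normalise, compare and serialise rCRS-relative mtDNA haplotypes.

A haplotype is the list of differences of a sample from the reference
within its sequenced range, written in the EMPOP/forensic notation:
``73G`` (substitution), ``309.1C`` (first inserted base after np 309),
``523del`` (deletion of np 523).  Reading frames are lists of inclusive
1-based ranges because the control region wraps the origin of the
circular molecule (nps 16024-16569 then 1-576).

Conventions fixed here and used throughout the package:

* coordinates are 1-based rCRS nps; ranges are inclusive;
* indels are placed at their 3'-most position on the plus strand;
* multi-base deletions are stored per position (``523del 524del`` is two
  variants, each contributing one difference);
* IUPAC ambiguity codes (point heteroplasmy) match any compatible base
  when computing distances, while haplotype *identity* uses exact tokens;
* length variants of the C-stretches around nps 16193, 309 and 573 are
  disregarded (insertions at those anchors are masked) under the default
  hotspot policy.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace

from .reference import ReferenceGenome

IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"), "B": frozenset("CGT"), "D": frozenset("AGT"),
    "H": frozenset("ACT"), "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

SUBSTITUTION = "substitution"
INSERTION = "insertion"
DELETION = "deletion"

_TOKEN_RE = re.compile(r"(\d+)(?:\.(\d+))?(DEL|[ACGTRYSWKMBDHVN])", re.IGNORECASE)


class HaplotypeParseError(ValueError):
    """A variant token does not match the <pos>[.<k>](<base>|del) grammar."""


class FrameError(ValueError):
    """A variant lies outside the reading frame, or frames are incompatible."""


@dataclass(frozen=True)
class Variant:
    """One difference from the reference at a 1-based np."""

    position: int
    insertion_index: int  # 0 for substitutions/deletions, >=1 for insertions
    kind: str
    derived: str  # IUPAC base(s); "" for deletions

    def __post_init__(self) -> None:
        if not 1 <= self.position <= 16569:
            raise ValueError(f"np {self.position} outside 1..16569")
        if self.kind not in (SUBSTITUTION, INSERTION, DELETION):
            raise ValueError(f"unknown variant kind {self.kind!r}")
        if (self.kind == INSERTION) != (self.insertion_index >= 1):
            raise ValueError("insertion_index >= 1 required iff kind is insertion")
        if self.kind == DELETION and self.derived:
            raise ValueError("deletions carry no derived base")
        if self.kind != DELETION and self.derived not in IUPAC:
            raise ValueError(f"derived state {self.derived!r} is not an IUPAC base")

    @property
    def token(self) -> str:
        if self.kind == DELETION:
            return f"{self.position}del"
        if self.kind == INSERTION:
            return f"{self.position}.{self.insertion_index}{self.derived}"
        return f"{self.position}{self.derived}"

    @property
    def site(self) -> tuple[int, int]:
        """The comparable site key: (np, insertion index)."""
        return (self.position, self.insertion_index)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.token


def substitution(position: int, base: str) -> Variant:
    return Variant(position, 0, SUBSTITUTION, base.upper())


def insertion(position: int, index: int, base: str) -> Variant:
    return Variant(position, index, INSERTION, base.upper())


def deletion(position: int) -> Variant:
    return Variant(position, 0, DELETION, "")


@dataclass(frozen=True)
class ReadingFrame:
    """Non-overlapping list of inclusive 1-based np ranges."""

    ranges: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        # canonical order: sorted by start np (makes equality structural;
        # the circular CR "wrap" is purely notational)
        rng = tuple(sorted((int(s), int(e)) for s, e in self.ranges))
        object.__setattr__(self, "ranges", rng)
        for s, e in rng:
            if not (1 <= s <= e <= 16569):
                raise FrameError(f"bad range {s}-{e}")
        for (_, e1), (s2, _) in zip(rng, rng[1:]):
            if s2 <= e1:
                raise FrameError("overlapping ranges in reading frame")

    def contains(self, position: int) -> bool:
        return any(s <= position <= e for s, e in self.ranges)

    def intersect(self, other: "ReadingFrame") -> "ReadingFrame":
        out = []
        for s1, e1 in self.ranges:
            for s2, e2 in other.ranges:
                s, e = max(s1, s2), min(e1, e2)
                if s <= e:
                    out.append((s, e))
        if not out:
            raise FrameError("empty reading-frame intersection")
        return ReadingFrame(tuple(sorted(out)))

    def positions(self) -> list[int]:
        """All nps in the frame, in range order (ranges as listed)."""
        return [p for s, e in self.ranges for p in range(s, e + 1)]

    def __len__(self) -> int:
        return sum(e - s + 1 for s, e in self.ranges)

    def __str__(self) -> str:
        return ";".join(f"{s}-{e}" for s, e in self.ranges)

    @classmethod
    def parse(cls, text: str) -> "ReadingFrame":
        """Parse a '16024-16569;1-576'-style range list."""
        ranges = []
        for chunk in text.replace(",", ";").split(";"):
            chunk = chunk.strip()
            if not chunk:
                continue
            m = re.fullmatch(r"(\d+)\s*-\s*(\d+)", chunk)
            if not m:
                raise FrameError(f"bad range specification {chunk!r}")
            ranges.append((int(m.group(1)), int(m.group(2))))
        if not ranges:
            raise FrameError("empty reading frame")
        return cls(tuple(ranges))


#: Named frame presets used in the study's comparison tables.
FRAME_CR = ReadingFrame(((16024, 16569), (1, 576)))
FRAME_HVS1_2 = ReadingFrame(((16080, 16193), (16194, 16365), (73, 300)))
FRAME_HVS1 = ReadingFrame(((16080, 16180), (16195, 16354)))
FRAMES = {"cr": FRAME_CR, "hvs1_2": FRAME_HVS1_2, "hvs1": FRAME_HVS1}


@dataclass(frozen=True)
class HotspotPolicy:
    """Which mutational hotspots to disregard when comparing haplotypes.

    The default masks length variants (insertions) of the C-stretches
    anchored at nps 16193, 309 and 573.
    """

    masked_insertion_anchors: frozenset[int] = frozenset({16193, 309, 573})
    masked_kinds: frozenset[str] = frozenset({INSERTION})

    def __post_init__(self) -> None:
        for np_ in self.masked_insertion_anchors:
            if not 1 <= np_ <= 16569:
                raise ValueError(f"hotspot anchor {np_} outside 1..16569")

    def masks(self, v: Variant) -> bool:
        return v.kind in self.masked_kinds and v.position in self.masked_insertion_anchors


DEFAULT_POLICY = HotspotPolicy()
NO_MASKING = HotspotPolicy(masked_insertion_anchors=frozenset())


@dataclass(frozen=True)
class Haplotype:
    """A sample's differences from the reference within its sequenced range."""

    variants: tuple[Variant, ...]
    frame: ReadingFrame
    sample_id: str = ""
    population: str = ""

    def __post_init__(self) -> None:
        vs = tuple(sorted(self.variants, key=lambda v: (v.position, v.insertion_index)))
        object.__setattr__(self, "variants", vs)
        seen = set()
        for v in vs:
            key = (v.position, v.insertion_index, v.kind)
            if key in seen:
                raise ValueError(f"duplicate variant {v.token}")
            seen.add(key)
            if not self.frame.contains(v.position):
                raise FrameError(f"variant {v.token} outside frame {self.frame}")

    def __len__(self) -> int:
        return len(self.variants)

    def variant_set(self) -> frozenset[Variant]:
        return frozenset(self.variants)


def parse_haplotype(
    text: str,
    frame: ReadingFrame,
    sample_id: str = "",
    population: str = "",
) -> Haplotype:
    """Parse whitespace-separated variant tokens into a Haplotype.

    Raises HaplotypeParseError naming the offending token, or FrameError
    for variants outside the frame.
    """
    variants = []
    for token in text.split():
        m = _TOKEN_RE.fullmatch(token)
        if not m:
            raise HaplotypeParseError(f"malformed variant token {token!r}")
        pos, ins, state = int(m.group(1)), m.group(2), m.group(3).upper()
        if ins is not None and int(ins) < 1:
            raise HaplotypeParseError(f"malformed variant token {token!r}")
        if state == "DEL":
            if ins is not None:
                raise HaplotypeParseError(f"malformed variant token {token!r}")
            variants.append(deletion(pos))
        elif ins is not None:
            variants.append(insertion(pos, int(ins), state))
        else:
            variants.append(substitution(pos, state))
    return Haplotype(tuple(variants), frame, sample_id, population)


def format_haplotype(h: Haplotype) -> str:
    """Serialise in canonical ascending-np order; inverse of parse_haplotype."""
    return " ".join(v.token for v in h.variants)


def trim_to_frame(h: Haplotype, frame: ReadingFrame) -> Haplotype:
    """Restrict a haplotype to the intersection of its frame with `frame`.

    An insertion at x.k belongs to the frame iff np x does.
    """
    inter = h.frame.intersect(frame)
    kept = tuple(v for v in h.variants if inter.contains(v.position))
    return Haplotype(kept, inter, h.sample_id, h.population)


def mask_hotspots(h: Haplotype, policy: HotspotPolicy = DEFAULT_POLICY) -> Haplotype:
    """Drop hotspot length variants; all other variants are untouched."""
    return replace(h, variants=tuple(v for v in h.variants if not policy.masks(v)))


def canonical_key(h: Haplotype, policy: HotspotPolicy = DEFAULT_POLICY) -> str:
    """Identity string used for haplotype counting: masked, canonical order."""
    return format_haplotype(mask_hotspots(h, policy))


def _compatible(a: str, b: str) -> bool:
    return bool(IUPAC[a] & IUPAC[b])


def pairwise_distance(
    h1: Haplotype, h2: Haplotype, policy: HotspotPolicy = DEFAULT_POLICY
) -> int:
    """Number of differing sites between two haplotypes on a shared frame.

    Sites present in only one masked variant set each count 1; a site where
    both carry a variant counts 0 if the states are IUPAC-compatible
    (same kind) and 1 otherwise.  Symmetric, and a metric over unambiguous
    states.
    """
    if h1.frame != h2.frame:
        raise FrameError("haplotypes must be trimmed to the same frame")
    m1 = {v.site: v for v in mask_hotspots(h1, policy).variants}
    m2 = {v.site: v for v in mask_hotspots(h2, policy).variants}
    d = 0
    for site in m1.keys() | m2.keys():
        a, b = m1.get(site), m2.get(site)
        if a is None or b is None:
            d += 1
        elif a.kind != b.kind:
            d += 1
        elif a.kind == DELETION:
            continue
        elif not _compatible(a.derived, b.derived):
            d += 1
    return d


# ---------------------------------------------------------------------------
# Sequence <-> variant-list conversion


def variants_to_sequence(h: Haplotype, ref: ReferenceGenome) -> str:
    """Apply a haplotype to the reference over its frame.

    Returns the sample's sequence as the concatenation of the frame ranges
    in their listed order; inverse of sequence_to_variants over the frame.
    """
    ins_at: dict[tuple[int, int], str] = {}
    sub_at: dict[int, str] = {}
    del_at: set[int] = set()
    for v in h.variants:
        if v.kind == SUBSTITUTION:
            sub_at[v.position] = v.derived
        elif v.kind == DELETION:
            del_at.add(v.position)
        else:
            ins_at[(v.position, v.insertion_index)] = v.derived
    out: list[str] = []
    for s, e in h.frame.ranges:
        for pos in range(s, e + 1):
            if pos not in del_at:
                out.append(sub_at.get(pos, ref.base(pos)))
            k = 1
            while (pos, k) in ins_at:
                out.append(ins_at[(pos, k)])
                k += 1
    return "".join(out)


def _right_shift_indels(ops: list[tuple[str, int, str]], ref_concat: str,
                        pos_map: list[int]) -> list[tuple[str, int, str]]:
    """Normalise indel placement to the 3'-most equivalent position.

    `ops` are (kind, ref_offset, base) with ref_offset an index into the
    concatenated reference region; deletions delete ref_concat[ref_offset],
    insertions insert `base` after ref_offset (-1 = before the region).
    Shifting is valid only within a contiguous run of reference positions.
    """
    n = len(ref_concat)

    def contiguous(i: int, j: int) -> bool:
        # offsets i..j map to consecutive nps (no jump across frame ranges)
        return pos_map[j] - pos_map[i] == j - i

    out = []
    taken = {off for kind, off, _ in ops if kind == "del"}
    for kind, off, base in ops:
        if kind == "del":
            b = ref_concat[off]
            j = off
            while (j + 1 < n and ref_concat[j + 1] == b and contiguous(off, j + 1)
                   and (j + 1) not in taken):
                j += 1
            taken.discard(off)
            taken.add(j)
            out.append((kind, j, base))
        elif kind == "ins":
            j = off
            while (j + 1 < n and ref_concat[j + 1] == base
                   and (off < 0 or contiguous(max(off, 0), j + 1))):
                j += 1
            out.append((kind, j, base))
        else:
            out.append((kind, off, base))
    return out


def sequence_to_variants(
    seq: str,
    ref: ReferenceGenome,
    frame: ReadingFrame,
    sample_id: str = "",
    population: str = "",
) -> Haplotype:
    """Align a sample sequence to the reference over `frame` and encode it.

    `seq` is the sample's sequence over the frame ranges, concatenated in
    their listed order (as produced by variants_to_sequence).  Indels are
    placed at the 3'-most equivalent np.
    """
    import edlib

    seq = seq.upper()
    bad = set(seq) - set(IUPAC)
    if bad:
        raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    pos_map = frame.positions()
    ref_concat = "".join(ref.base(p) for p in pos_map)

    ops: list[tuple[str, int, str]] = []
    if seq == ref_concat:
        pass
    else:
        aln = edlib.align(seq, ref_concat, task="path", mode="NW")
        ref_off = -1
        qry_off = -1
        for count, op in re.findall(r"(\d+)([=XIDM])", aln["cigar"]):
            count = int(count)
            if op in "=M":
                for _ in range(count):
                    ref_off += 1
                    qry_off += 1
                    if op == "M" and seq[qry_off] != ref_concat[ref_off]:
                        ops.append(("sub", ref_off, seq[qry_off]))
            elif op == "X":
                for _ in range(count):
                    ref_off += 1
                    qry_off += 1
                    ops.append(("sub", ref_off, seq[qry_off]))
            elif op == "D":  # in reference, absent from sample
                for _ in range(count):
                    ref_off += 1
                    ops.append(("del", ref_off, ""))
            else:  # "I": present in sample, absent from reference
                for _ in range(count):
                    qry_off += 1
                    ops.append(("ins", ref_off, seq[qry_off]))
        ops = _right_shift_indels(ops, ref_concat, pos_map)

    variants: list[Variant] = []
    ins_counter: dict[int, int] = {}
    for kind, off, base in sorted(ops, key=lambda t: (t[1], t[0] != "ins")):
        if kind == "sub":
            variants.append(substitution(pos_map[off], base))
        elif kind == "del":
            variants.append(deletion(pos_map[off]))
        else:
            anchor = pos_map[off] if off >= 0 else pos_map[0] - 1
            k = ins_counter.get(anchor, 0) + 1
            ins_counter[anchor] = k
            variants.append(insertion(anchor, k, base))
    return Haplotype(tuple(variants), frame, sample_id, population)


# ---------------------------------------------------------------------------
# Haplotype-table I/O (TSV dialect: SampleID, Population, Range, Variants)


def read_haplotype_table(path) -> list[Haplotype]:
    import csv

    out = []
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh, delimiter="\t")
                if r and not r[0].startswith("#")]
    header = rows[0]
    idx = {name: header.index(name) for name in ("SampleID", "Population", "Range", "Variants")}
    for row in rows[1:]:
        frame = ReadingFrame.parse(row[idx["Range"]])
        out.append(parse_haplotype(row[idx["Variants"]], frame,
                                   sample_id=row[idx["SampleID"]],
                                   population=row[idx["Population"]]))
    return out


def write_haplotype_table(haplotypes, path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("SampleID\tPopulation\tRange\tVariants\n")
        for h in haplotypes:
            fh.write(f"{h.sample_id}\t{h.population}\t{h.frame}\t{format_haplotype(h)}\n")
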