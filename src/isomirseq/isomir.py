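"""Seven-way isomiR classification against a hairpin-anchored reference.

Each read is interpreted against every annotated mature miRNA by sliding
its 5' end within a small window around the canonical 5' end.  For a
given (mature, 5' offset) the 3' offset is fixed by the read length, so
an interpretation is fully described by:

* ``offset5`` — signed 5' shift (positive = 5' deletion, negative = 5'
  extension, which must be templated by the hairpin: non-templated 5'
  additions are not modelled);
* ``offset3`` — signed 3' shift (positive = 3' extension, negative =
  3' trimming);
* the substitution set over the template-aligned portion;
* for 3' extensions, a unique greedy decomposition into a templated part
  (bases matching the hairpin downstream of the canonical 3' end, taken
  as far as they match) and a non-templated addition (NTA) tail — the
  remainder.  All-A tails are adenylation, all-T(U) tails uridylation.

The best interpretation minimizes, in order: substitution count, total
end shift |offset5|+|offset3|, NTA tail length, |offset5|, then mature
name.  Exact ties across matures are resolved by fractional assignment.

Categories: canonical (no change), substitution, del3p / add3p, del5p /
add5p (single-end changes) and mixed (two or more change types).  A 5'
shift moves the seed (bases 2-8) by exactly ``offset5`` — the "seed
shift" that changes targeting specificity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from .ingest import CollapsedRead
from .reference import HairpinRecord, MatureAnnotation, ReferenceSet


class IsomiRCategory(str, Enum):
    CANONICAL = "canonical"
    SUBSTITUTION = "substitution"
    DEL3P = "del3p"
    ADD3P = "add3p"
    DEL5P = "del5p"
    ADD5P = "add5p"
    MIXED = "mixed"


class TailKind(str, Enum):
    NONE = "none"
    TEMPLATED = "templated"
    ADENYLATED = "adenylated"
    URIDYLATED = "uridylated"
    OTHER = "other"


@dataclass(frozen=True)
class ClassifierLimits:
    """Search window for interpretations.

    Defaults cover every variant class reported in chondrocyte small-RNA
    libraries (5' shifts up to 3 nt, 3' trims/extensions up to 5 nt, at
    most 2 internal substitutions) while keeping interpretations sparse
    enough for the minimal-edit choice to be meaningful.
    """

    max_offset5: int = 3
    max_del3: int = 5
    max_add3: int = 5
    max_subs: int = 2


DEFAULT_LIMITS = ClassifierLimits()


@dataclass(frozen=True)
class AlignmentCandidate:
    """One interpretation of a read as a variant of one mature."""

    mature_name: str
    offset5: int
    offset3: int
    substitutions: tuple[tuple[int, str, str], ...]  # (read_pos, ref, read)
    templated_ext3: int
    nta_tail: str

    @property
    def sort_key(self) -> tuple:
        # Ordered minimal-edit key; trailing offsets make the order total.
        return (
            len(self.substitutions),
            abs(self.offset5) + abs(self.offset3),
            len(self.nta_tail),
            abs(self.offset5),
            self.mature_name,
            self.offset5,
            self.offset3,
        )

    @property
    def tie_key(self) -> tuple:
        """Key compared across matures for fractional assignment."""
        return (
            len(self.substitutions),
            abs(self.offset5) + abs(self.offset3),
            len(self.nta_tail),
            abs(self.offset5),
        )


@dataclass(frozen=True)
class IsomiRCall:
    read: CollapsedRead
    candidate: AlignmentCandidate
    category: IsomiRCategory
    tail: TailKind
    seed: str
    assigned_fraction: float


def seed_of(sequence: str) -> str:
    """Bases 2-8 (1-based) — the target-pairing seed region."""
    if len(sequence) < 8:
        raise ValueError(f"sequence shorter than 8 nt has no seed: {sequence!r}")
    return sequence[1:8]


def seed_shift(call: IsomiRCall, mature: MatureAnnotation | None = None) -> int:
    """Displacement of the seed relative to the canonical mature.

    A 5' offset shifts the seed window by exactly that many bases;
    3'-only variants leave the seed in place.
    """
    return call.candidate.offset5


def classify_tail(candidate: AlignmentCandidate) -> TailKind:
    tail = candidate.nta_tail
    if tail:
        bases = set(tail)
        if bases == {"A"}:
            return TailKind.ADENYLATED
        if bases == {"T"}:
            return TailKind.URIDYLATED
        return TailKind.OTHER
    if candidate.offset3 > 0:
        return TailKind.TEMPLATED
    return TailKind.NONE


def classify_candidate(candidate: AlignmentCandidate) -> IsomiRCategory:
    """Map an interpretation to one of the seven categories."""
    changes = sum(
        (
            candidate.offset5 != 0,
            candidate.offset3 != 0,
            len(candidate.substitutions) > 0,
        )
    )
    if changes == 0:
        return IsomiRCategory.CANONICAL
    if changes >= 2:
        return IsomiRCategory.MIXED
    if candidate.substitutions:
        return IsomiRCategory.SUBSTITUTION
    if candidate.offset5 > 0:
        return IsomiRCategory.DEL5P
    if candidate.offset5 < 0:
        return IsomiRCategory.ADD5P
    if candidate.offset3 < 0:
        return IsomiRCategory.DEL3P
    return IsomiRCategory.ADD3P


def enumerate_candidates(
    read: str,
    mature: MatureAnnotation,
    hairpin: HairpinRecord,
    limits: ClassifierLimits = DEFAULT_LIMITS,
) -> list[AlignmentCandidate]:
    """All valid interpretations of ``read`` as a variant of ``mature``.

    For each 5' offset the read is anchored on the hairpin at
    ``mature.start + offset5``; the 3' offset follows from the read
    length.  5' extensions must match the hairpin exactly (no 5' NTA);
    substitutions are counted over the template-aligned portion only,
    never inside the NTA tail; 3' extensions decompose greedily into
    templated bases then tail.
    """
    out: list[AlignmentCandidate] = []
    hseq = hairpin.sequence
    L = hairpin.length
    rlen = len(read)
    for offset5 in range(-limits.max_offset5, limits.max_offset5 + 1):
        s = mature.start + offset5
        if s < 0:
            continue  # template span would exit the hairpin upstream
        offset3 = (s + rlen) - mature.end
        if offset3 < -limits.max_del3 or offset3 > limits.max_add3:
            continue
        body_len = rlen - max(offset3, 0)  # read bases aligned to [s, mature.end)
        if body_len <= 0:
            continue
        if offset5 < 0:
            # templated 5' extension: must match the hairpin exactly
            ext5 = -offset5
            if read[:ext5] != hseq[s : s + ext5]:
                continue
        # substitutions over the template-aligned body
        if s + body_len > L:
            continue  # template span exits the hairpin downstream
        subs: list[tuple[int, str, str]] = []
        if read[:body_len] != hseq[s : s + body_len]:
            start_cmp = max(0, -offset5)  # 5' extension already verified exact
            for i in range(start_cmp, body_len):
                if read[i] != hseq[s + i]:
                    subs.append((i, hseq[s + i], read[i]))
                    if len(subs) > limits.max_subs:
                        break
            if len(subs) > limits.max_subs:
                continue
        # greedy templated decomposition of any 3' extension
        templated_ext3 = 0
        tail = ""
        if offset3 > 0:
            ext = read[body_len:]
            while (
                templated_ext3 < offset3
                and mature.end + templated_ext3 < L
                and ext[templated_ext3] == hseq[mature.end + templated_ext3]
            ):
                templated_ext3 += 1
            tail = ext[templated_ext3:]
        out.append(
            AlignmentCandidate(
                mature_name=mature.name,
                offset5=offset5,
                offset3=offset3,
                substitutions=tuple(subs),
                templated_ext3=templated_ext3,
                nta_tail=tail,
            )
        )
    return out


def select_best_candidate(
    candidates: Sequence[AlignmentCandidate],
) -> AlignmentCandidate:
    """Minimal-edit interpretation under the ordered key; deterministic."""
    if not candidates:
        raise ValueError("no candidates to select from")
    return min(candidates, key=lambda c: c.sort_key)


def classify_read(
    read: CollapsedRead,
    ref: ReferenceSet,
    limits: ClassifierLimits = DEFAULT_LIMITS,
) -> list[IsomiRCall]:
    """Assign a collapsed read; empty list means unassigned.

    Each mature contributes its own best interpretation; the global
    minimum wins.  When the minimal edit signature ties across k
    matures, each receives a call with assigned_fraction 1/k (fractional
    multi-mapping keeps counts conserved and deterministic).
    """
    per_mature: list[AlignmentCandidate] = []
    for mature in ref.matures:
        cands = enumerate_candidates(
            read.sequence, mature, ref.hairpins[mature.hairpin_id], limits
        )
        if cands:
            per_mature.append(select_best_candidate(cands))
    if not per_mature:
        return []
    best = min(per_mature, key=lambda c: c.sort_key)
    winners = sorted(
        (c for c in per_mature if c.tie_key == best.tie_key),
        key=lambda c: c.sort_key,
    )
    fraction = 1.0 / len(winners)
    calls = []
    for cand in winners:
        calls.append(
            IsomiRCall(
                read=read,
                candidate=cand,
                category=classify_candidate(cand),
                tail=classify_tail(cand),
                seed=seed_of(read.sequence),
                assigned_fraction=fraction,
            )
        )
    return calls


def classify_library(
    collapsed: Iterable[CollapsedRead],
    ref: ReferenceSet,
    limits: ClassifierLimits = DEFAULT_LIMITS,
) -> tuple[list[IsomiRCall], list[CollapsedRead]]:
    """Classify a whole collapsed library; returns (calls, unassigned)."""
    calls: list[IsomiRCall] = []
    unassigned: list[CollapsedRead] = []
    for read in collapsed:
        got = classify_read(read, ref, limits)
        if got:
            calls.extend(got)
        else:
            unassigned.append(read)
    return calls, unassigned


def encode_substitutions(subs: Sequence[tuple[int, str, str]]) -> str:
    """Canonical string encoding, e.g. ``4:G>A;11:C>T``."""
    return ";".join(f"{pos}:{ref}>{alt}" for pos, ref, alt in sorted(subs))


def write_calls_tsv(calls: Iterable[IsomiRCall], path: str | Path) -> None:
    cols = [
        "sequence",
        "count",
        "sample_id",
        "mature",
        "offset5",
        "offset3",
        "substitutions",
        "tail",
        "tail_kind",
        "category",
        "seed",
        "fraction",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for c in calls:
            fh.write(
                "\t".join(
                    [
                        c.read.sequence,
                        str(c.read.count),
                        c.read.sample_id,
                        c.candidate.mature_name,
                        str(c.candidate.offset5),
                        str(c.candidate.offset3),
                        encode_substitutions(c.candidate.substitutions),
                        c.candidate.nta_tail,
                        c.tail.value,
                        c.category.value,
                        c.seed,
                        f"{c.assigned_fraction:.6g}",
                    ]
                )
                + "\n"
            )
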