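"""miRBase-style reference handling.

A reference is a set of precursor hairpins plus mature miRNA annotations
located on them.  Matures may be located either by GFF3 coordinates
(miRBase dialect: ``miRNA_primary_transcript`` / ``miRNA`` features with
``Name`` attributes) or, when no GFF3 is given, by exact string search of
the mature sequence on its hairpin.

Coordinates are 0-based half-open internally; GFF3 input (1-based,
inclusive) is converted on load.  RNA alphabets are normalized U->T on
input, and writers echo the alphabet convention the reference came in
with.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO

logger = logging.getLogger(__name__)

Arm = Literal["5p", "3p"]


class ReferenceConsistencyError(ValueError):
    """A mature annotation does not agree with its hairpin sequence."""


class MatureNotFoundError(ReferenceConsistencyError):
    """A mature sequence has no exact occurrence on its hairpin."""


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


@dataclass(frozen=True)
class HairpinRecord:
    """A precursor (pre-miRNA) hairpin sequence."""

    id: str
    sequence: str  # ACGT after U->T normalization

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ReferenceConsistencyError(f"hairpin {self.id!r} has empty sequence")
        bad = set(self.sequence) - set("ACGT")
        if bad:
            raise ReferenceConsistencyError(
                f"hairpin {self.id!r} contains non-ACGT characters {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MatureAnnotation:
    """A mature miRNA located on its precursor hairpin.

    ``start``/``end`` are 0-based half-open coordinates on the hairpin;
    ``arm`` says which side of the hairpin duplex the mature comes from.
    """

    name: str
    hairpin_id: str
    start: int
    end: int
    arm: Arm
    canonical_sequence: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ReferenceConsistencyError(
                f"mature {self.name!r}: invalid interval [{self.start}, {self.end})"
            )
        if not (16 <= self.end - self.start <= 30):
            raise ReferenceConsistencyError(
                f"mature {self.name!r}: length {self.end - self.start} outside [16, 30]"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ReferenceSet:
    """Hairpins plus located mature annotations."""

    hairpins: dict[str, HairpinRecord]
    matures: list[MatureAnnotation]
    rna_alphabet: bool = False  # True if the input FASTA used U (RNA)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for m in self.matures:
            if m.name in seen:
                raise ReferenceConsistencyError(f"duplicate mature name {m.name!r}")
            seen.add(m.name)
            hp = self.hairpins.get(m.hairpin_id)
            if hp is None:
                raise ReferenceConsistencyError(
                    f"mature {m.name!r} references unknown hairpin {m.hairpin_id!r}"
                )
            if m.end > hp.length:
                raise ReferenceConsistencyError(
                    f"mature {m.name!r}: end {m.end} beyond hairpin length {hp.length}"
                )
            if hp.sequence[m.start : m.end] != m.canonical_sequence:
                raise ReferenceConsistencyError(
                    f"mature {m.name!r}: canonical sequence does not match "
                    f"hairpin {m.hairpin_id!r} at [{m.start}, {m.end})"
                )

    def mature_by_name(self, name: str) -> MatureAnnotation:
        for m in self.matures:
            if m.name == name:
                return m
        raise KeyError(name)

    def matures_of(self, hairpin_id: str) -> list[MatureAnnotation]:
        return [m for m in self.matures if m.hairpin_id == hairpin_id]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReferenceSet):
            return NotImplemented
        return (
            self.hairpins == other.hairpins
            and sorted(self.matures, key=lambda m: m.name)
            == sorted(other.matures, key=lambda m: m.name)
        )


def locate_mature(mature_seq: str, hairpin: HairpinRecord) -> tuple[int, int]:
    """Locate a mature sequence on its hairpin by exact search.

    Returns 0-based half-open coordinates of the leftmost occurrence.
    Raises :class:`MatureNotFoundError` if there is none; logs a warning
    (leftmost used) if there are several.
    """
    seq = _normalize(mature_seq)
    if len(seq) < 16:
        raise ValueError(f"mature sequence shorter than 16 nt: {len(seq)}")
    start = hairpin.sequence.find(seq)
    if start < 0:
        raise MatureNotFoundError(
            f"mature sequence not found on hairpin {hairpin.id!r}: {mature_seq}"
        )
    second = hairpin.sequence.find(seq, start + 1)
    if second >= 0:
        logger.warning(
            "mature sequence occurs more than once on hairpin %s; using leftmost "
            "occurrence at %d",
            hairpin.id,
            start,
        )
        warnings.warn(
            f"mature sequence occurs multiple times on hairpin {hairpin.id}; "
            "leftmost occurrence used",
            stacklevel=2,
        )
    return start, start + len(seq)


def arm_of(mature: MatureAnnotation, hairpin: HairpinRecord) -> Arm:
    """Infer the arm (5p/3p) of a mature from its position on the hairpin.

    5p iff the mature midpoint lies in the 5' half of the hairpin; an
    exactly centered mature is assigned 3p (deterministic tie rule).
    """
    midpoint = (mature.start + mature.end) / 2
    return "5p" if midpoint < hairpin.length / 2 else "3p"


def _read_fasta(path: Path) -> tuple[dict[str, str], bool]:
    records: dict[str, str] = {}
    saw_u = False
    for rec in SeqIO.parse(str(path), "fasta"):
        raw = str(rec.seq).upper()
        if "U" in raw:
            saw_u = True
        records[rec.id] = _normalize(raw)
    return records, saw_u


def _parse_gff3(path: Path) -> list[dict]:
    """Parse a miRBase-dialect GFF3 into feature dicts.

    Only ``miRNA_primary_transcript`` and ``miRNA`` features are kept.
    Coordinates stay 1-based inclusive here; the caller converts.
    """
    feats: list[dict] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"malformed GFF3 line (expected 9 columns): {line!r}")
            attrs = {}
            for chunk in cols[8].split(";"):
                chunk = chunk.strip()
                if chunk and "=" in chunk:
                    k, v = chunk.split("=", 1)
                    attrs[k] = v
            feats.append(
                {
                    "seqid": cols[0],
                    "type": cols[2],
                    "start": int(cols[3]),
                    "end": int(cols[4]),
                    "attrs": attrs,
                }
            )
    return feats


def load_reference(
    hairpin_fasta: str | Path,
    mature_fasta: str | Path,
    coords_gff3: str | Path | None = None,
) -> ReferenceSet:
    """Load hairpin + mature FASTA (and optional GFF3 coordinates).

    Without a GFF3, matures are located by exact search on every hairpin
    whose ID prefixes their name, falling back to a search over all
    hairpins.  With a GFF3, the ``miRNA`` features give coordinates
    (converted from 1-based inclusive to 0-based half-open) and the
    hairpin pairing; an ``arm`` or ``Name``-suffix arm label, when
    present, overrides midpoint inference.

    Raises ``FileNotFoundError`` for missing files and
    :class:`ReferenceConsistencyError` when a mature cannot be
    reconciled with its hairpin.
    """
    hairpin_fasta = Path(hairpin_fasta)
    mature_fasta = Path(mature_fasta)
    for p in (hairpin_fasta, mature_fasta):
        if not p.exists():
            raise FileNotFoundError(p)
    hp_seqs, hp_rna = _read_fasta(hairpin_fasta)
    mat_seqs, mat_rna = _read_fasta(mature_fasta)
    hairpins = {hid: HairpinRecord(hid, seq) for hid, seq in hp_seqs.items()}

    matures: list[MatureAnnotation] = []
    if coords_gff3 is not None:
        coords_gff3 = Path(coords_gff3)
        if not coords_gff3.exists():
            raise FileNotFoundError(coords_gff3)
        feats = _parse_gff3(coords_gff3)
        primaries = {
            f["attrs"].get("Name", f["seqid"]): f["seqid"]
            for f in feats
            if f["type"] == "miRNA_primary_transcript"
        }
        for f in feats:
            if f["type"] != "miRNA":
                continue
            name = f["attrs"].get("Name")
            if name is None:
                raise ValueError("miRNA feature without Name attribute in GFF3")
            hairpin_id = f["attrs"].get("Derives_from", f["seqid"])
            hairpin_id = primaries.get(hairpin_id, hairpin_id)
            if hairpin_id not in hairpins:
                raise ReferenceConsistencyError(
                    f"GFF3 mature {name!r} references unknown hairpin {hairpin_id!r}"
                )
            hp = hairpins[hairpin_id]
            start, end = f["start"] - 1, f["end"]  # to 0-based half-open
            canon = hp.sequence[start:end]
            if name in mat_seqs and mat_seqs[name] != canon:
                raise ReferenceConsistencyError(
                    f"mature {name!r}: GFF3 coordinates disagree with mature FASTA"
                )
            arm = f["attrs"].get("arm")
            if arm not in ("5p", "3p"):
                # miRBase encodes the arm as a -5p/-3p name suffix
                arm = name[-2:] if name.endswith(("-5p", "-3p")) else None
            m = MatureAnnotation(name, hairpin_id, start, end, arm or "3p", canon)
            if arm is None:
                m = replace(m, arm=arm_of(m, hp))
            matures.append(m)
    else:
        for name, seq in mat_seqs.items():
            hit: MatureAnnotation | None = None
            for hid, hp in hairpins.items():
                try:
                    start, end = locate_mature(seq, hp)
                except MatureNotFoundError:
                    continue
                cand = MatureAnnotation(name, hid, start, end, "3p", seq)
                cand = replace(cand, arm=arm_of(cand, hp))
                if hit is None:
                    hit = cand
                else:
                    logger.warning(
                        "mature %s occurs on several hairpins; keeping %s",
                        name,
                        hit.hairpin_id,
                    )
            if hit is None:
                raise MatureNotFoundError(
                    f"mature sequence not found on any hairpin: {name}"
                )
            matures.append(hit)

    return ReferenceSet(
        hairpins=hairpins, matures=matures, rna_alphabet=hp_rna or mat_rna
    )


def write_reference(
    ref: ReferenceSet,
    hairpin_fasta: str | Path,
    mature_fasta: str | Path,
    coords_gff3: str | Path | None = None,
) -> None:
    """Write a ReferenceSet back out as FASTA (+ optional GFF3).

    Sequences are written in the alphabet the reference was loaded with
    (T->U if it came in as RNA).
    """

    def echo(seq: str) -> str:
        return seq.replace("T", "U") if ref.rna_alphabet else seq

    with open(hairpin_fasta, "w") as fh:
        for hid in sorted(ref.hairpins):
            fh.write(f">{hid}\n{echo(ref.hairpins[hid].sequence)}\n")
    with open(mature_fasta, "w") as fh:
        for m in sorted(ref.matures, key=lambda m: m.name):
            fh.write(f">{m.name}\n{echo(m.canonical_sequence)}\n")
    if coords_gff3 is not None:
        with open(coords_gff3, "w") as fh:
            fh.write("##gff-version 3\n")
            for hid in sorted(ref.hairpins):
                hp = ref.hairpins[hid]
                fh.write(
                    f"{hid}\t.\tmiRNA_primary_transcript\t1\t{hp.length}\t.\t+\t.\t"
                    f"ID={hid};Name={hid}\n"
                )
                for m in sorted(ref.matures_of(hid), key=lambda m: m.start):
                    fh.write(
                        f"{hid}\t.\tmiRNA\t{m.start + 1}\t{m.end}\t.\t+\t.\t"
                        f"ID={m.name};Name={m.name};Derives_from={hid};arm={m.arm}\n"
                    )


def iter_mature_hairpin(ref: ReferenceSet) -> Iterable[tuple[MatureAnnotation, HairpinRecord]]:
    for m in ref.matures:
        yield m, ref.hairpins[m.hairpin_id]
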