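"""Synthetic small-RNA references, libraries and RIP experiments.

The generator emulates the salient structure of chondrocyte small-RNA
libraries: 22-nt mature miRNAs on both arms of random precursor
hairpins, a skewed abundance distribution across matures, a realistic
canonical/isomiR category mixture (about half canonical, with 3'
deletions dominating the variant mass, then 3' additions, then rare 5'
shifts, mixed and substitution forms), non-templated A/U tails, optional
per-base sequencing error, and paired RIP/input libraries with planted
log2 fold changes.  Every read is emitted together with a truth record,
so classifier recovery can be measured exactly.

Mature 22-mers and all their +/-3-shifted windows are screened for
uniqueness across the whole reference at construction time, making the
planted interpretation of every error-free read unambiguous.

All randomness flows from a single integer seed through one
``numpy.random.Generator``; the draw order is: hairpin construction,
per-mature abundances, then per-read (mature, category, edit, error)
draws in read order.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .quantify import VariantKey
from .reference import (
    HairpinRecord,
    MatureAnnotation,
    ReferenceSet,
    write_reference,
)

BASES = "ACGT"
MATURE_LEN = 22
_QUAL_CHAR = chr(35 + 33)  # constant Phred 35

# Category mixture shaped like deeply sequenced primary-cell libraries:
# ~48% canonical; the variant mass splits 71.1 : 15.4 : 3 : 2 : 1 : 1
# across del3p/add3p/add5p/del5p/mixed/substitution (normalized).
_VARIANT_SPLIT = {
    "del3p": 71.1,
    "add3p": 15.4,
    "add5p": 3.0,
    "del5p": 2.0,
    "mixed": 1.0,
    "substitution": 1.0,
}
_SPLIT_TOTAL = sum(_VARIANT_SPLIT.values())
DEFAULT_CATEGORY_PROPORTIONS = {
    "canonical": 0.48,
    **{k: 0.52 * v / _SPLIT_TOTAL for k, v in _VARIANT_SPLIT.items()},
}


@dataclass
class SimConfig:
    """Generator settings; defaults are the package's study conditions."""

    n_hairpins: int = 20
    matures_per_hairpin: int = 2
    n_reads: int = 10_000
    category_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_PROPORTIONS)
    )
    # per-end offset magnitude distributions (magnitude -> weight)
    del3_weights: dict[int, float] = field(
        default_factory=lambda: {1: 0.55, 2: 0.25, 3: 0.12, 4: 0.05, 5: 0.03}
    )
    add3_weights: dict[int, float] = field(
        default_factory=lambda: {1: 0.6, 2: 0.3, 3: 0.1}
    )
    offset5_weights: dict[int, float] = field(
        default_factory=lambda: {1: 0.7, 2: 0.2, 3: 0.1}
    )
    # 3' additions: fraction that are purely templated extensions;
    # the rest carry an NTA tail with this base composition.
    p_templated_add3: float = 0.3
    nta_composition: dict[str, float] = field(
        default_factory=lambda: {"p_A": 0.60, "p_U": 0.35, "p_other": 0.05}
    )
    # probability a substitution read carries a second substitution
    substitution_rate: float = 0.2
    sequencing_error_rate: float = 0.0
    length_mode: int = MATURE_LEN
    abundance_sigma: float = 1.0  # log-normal spread across matures
    rng_seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.category_proportions.values())
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(
                f"category_proportions must sum to 1, got {total:.6g}"
            )
        for name, p in self.category_proportions.items():
            if not 0 <= p <= 1:
                raise ValueError(f"proportion {name} outside [0,1]: {p}")
        nta_total = sum(self.nta_composition.values())
        if not np.isclose(nta_total, 1.0, atol=1e-9):
            raise ValueError("nta_composition must sum to 1")


@dataclass(frozen=True)
class TruthRecord:
    read_id: str
    mature_name: str
    category: str
    offset5: int
    offset3: int
    tail: str
    had_seq_error: bool


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def _count_occurrences(seq: str, window: str, limit: int = 2) -> int:
    """Overlapping occurrence count, capped at ``limit``."""
    hits = 0
    start = 0
    while hits < limit:
        i = seq.find(window, start)
        if i < 0:
            break
        hits += 1
        start = i + 1
    return hits


def _mature_windows(hairpin_seq: str, start: int, shift: int = 3) -> list[str]:
    out = []
    for k in range(-shift, shift + 1):
        s = start + k
        if 0 <= s and s + MATURE_LEN <= len(hairpin_seq):
            out.append(hairpin_seq[s : s + MATURE_LEN])
    return out


def make_reference(
    n_hairpins: int,
    rng_seed: int,
    matures_per_hairpin: int = 2,
    out_dir: str | Path | None = None,
) -> ReferenceSet:
    """Random reference with unambiguously placed 22-nt matures.

    Each hairpin is flank + 5p mature + loop + 3p mature + flank
    (total 60-82 nt).  A hairpin is accepted only if every mature
    window, and all its +/-3 nt shifts, occurs exactly once across the
    entire reference, so that a read carrying edits within the
    classifier's search window has a single truthful interpretation.
    Deterministic for a fixed seed.  When ``out_dir`` is given, hairpin
    and mature FASTA plus a GFF3 are written there.
    """
    if n_hairpins < 1:
        raise ValueError("n_hairpins must be >= 1")
    if matures_per_hairpin not in (1, 2):
        raise ValueError("matures_per_hairpin must be 1 or 2")
    rng = np.random.default_rng(rng_seed)
    hairpins: dict[str, HairpinRecord] = {}
    matures: list[MatureAnnotation] = []
    accepted_seqs: list[str] = []
    accepted_windows: list[str] = []
    for i in range(n_hairpins):
        hid = f"hp-{i + 1:04d}"
        for _attempt in range(200):
            flank5 = int(rng.integers(4, 11))
            loop = int(rng.integers(8, 19))
            flank3 = int(rng.integers(4, 11))
            seq = _random_seq(
                rng, flank5 + MATURE_LEN + loop + MATURE_LEN + flank3
            )
            s5 = flank5
            s3 = flank5 + MATURE_LEN + loop
            starts = [s5, s3] if matures_per_hairpin == 2 else [s5]
            new_windows: list[str] = []
            for start in starts:
                new_windows.extend(_mature_windows(seq, start))
            # each new window must occur exactly once in the whole
            # reference, and no established window may recur here
            ok = all(
                _count_occurrences(seq, w) == 1 for w in new_windows
            ) and all(
                _count_occurrences(old, w) == 0
                for w in new_windows
                for old in accepted_seqs
            ) and all(
                _count_occurrences(seq, w) == 0 for w in accepted_windows
            )
            if ok:
                break
        else:  # pragma: no cover - astronomically unlikely with random 22-mers
            raise RuntimeError(f"could not place unique matures for {hid}")
        accepted_seqs.append(seq)
        accepted_windows.extend(new_windows)
        hp = HairpinRecord(hid, seq)
        hairpins[hid] = hp
        for start, arm in zip(starts, ["5p", "3p"]):
            matures.append(
                MatureAnnotation(
                    name=f"{hid}-{arm}",
                    hairpin_id=hid,
                    start=start,
                    end=start + MATURE_LEN,
                    arm=arm,  # type: ignore[arg-type]
                    canonical_sequence=seq[start : start + MATURE_LEN],
                )
            )
    ref = ReferenceSet(hairpins=hairpins, matures=matures)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_reference(
            ref,
            out_dir / "hairpin.fa",
            out_dir / "mature.fa",
            out_dir / "coords.gff3",
        )
    return ref


def _weighted_choice(rng: np.random.Generator, weights: dict[int, float]) -> int:
    keys = sorted(weights)
    probs = np.array([weights[k] for k in keys], dtype=float)
    probs /= probs.sum()
    return int(rng.choice(keys, p=probs))


def _draw_tail(rng: np.random.Generator, length: int, comp: dict[str, float]) -> str:
    kind = rng.choice(
        ["A", "U", "other"], p=[comp["p_A"], comp["p_U"], comp["p_other"]]
    )
    if kind == "A":
        return "A" * length
    if kind == "U":
        return "T" * length
    return _random_seq(rng, length)


def _greedy_tail(ext: str, hairpin_seq: str, mature_end: int) -> tuple[int, str]:
    """Greedy templated/NTA decomposition of a 3' extension (truth side)."""
    t = 0
    while (
        t < len(ext)
        and mature_end + t < len(hairpin_seq)
        and ext[t] == hairpin_seq[mature_end + t]
    ):
        t += 1
    return t, ext[t:]


def _apply_5p(
    rng: np.random.Generator,
    cfg: SimConfig,
    mature: MatureAnnotation,
    hairpin: HairpinRecord,
    kind: str,
) -> tuple[int, str]:
    """Return (offset5, 5'-adjusted core sequence)."""
    canon = mature.canonical_sequence
    if kind == "del5p":
        d = _weighted_choice(rng, cfg.offset5_weights)
        return d, canon[d:]
    d = _weighted_choice(rng, cfg.offset5_weights)
    d = min(d, mature.start)  # templated extension cannot exit the hairpin
    if d == 0:
        return 0, canon
    return -d, hairpin.sequence[mature.start - d : mature.start] + canon


def _apply_3p(
    rng: np.random.Generator,
    cfg: SimConfig,
    hairpin: HairpinRecord,
    mature: MatureAnnotation,
    core: str,
    kind: str,
) -> tuple[int, str, str]:
    """Return (offset3, tail-after-greedy, sequence with 3' change applied)."""
    if kind == "del3p":
        d = _weighted_choice(rng, cfg.del3_weights)
        d = min(d, len(core) - 16)  # keep reads classifiable (>=16 nt)
        if d == 0:
            return 0, "", core
        return -d, "", core[:-d]
    d = _weighted_choice(rng, cfg.add3_weights)
    room = hairpin.length - mature.end
    if rng.random() < cfg.p_templated_add3 and room >= 1:
        t = min(d, room)
        ext = hairpin.sequence[mature.end : mature.end + t]
    else:
        ext = _draw_tail(rng, d, cfg.nta_composition)
    t_len, tail = _greedy_tail(ext, hairpin.sequence, mature.end)
    return len(ext), tail, core + ext


def _apply_substitutions(
    rng: np.random.Generator, cfg: SimConfig, seq: str
) -> str:
    n_subs = 1 + int(rng.random() < cfg.substitution_rate)
    positions = rng.choice(len(seq), size=n_subs, replace=False)
    chars = list(seq)
    for pos in sorted(int(p) for p in positions):
        alternatives = [b for b in BASES if b != chars[pos]]
        chars[pos] = alternatives[int(rng.integers(0, 3))]
    return "".join(chars)


def synthesize_variant(
    rng: np.random.Generator,
    cfg: SimConfig,
    mature: MatureAnnotation,
    hairpin: HairpinRecord,
    category: str,
) -> tuple[str, int, int, str]:
    """Construct one variant read of the given category.

    Returns (sequence, offset5, offset3, nta_tail) where the tail is the
    post-greedy non-templated part (a planted 'A' that happens to match
    the template is truthfully templated).  Falls back to canonical when
    hairpin geometry cannot host the requested change (recorded as
    canonical truth).
    """
    canon = mature.canonical_sequence
    if category == "canonical":
        return canon, 0, 0, ""
    if category == "substitution":
        return _apply_substitutions(rng, cfg, canon), 0, 0, ""
    if category == "del5p" or category == "add5p":
        off5, seq = _apply_5p(
            rng, cfg, mature, hairpin, "del5p" if category == "del5p" else "add5p"
        )
        return seq, off5, 0, ""
    if category == "del3p" or category == "add3p":
        off3, tail, seq = _apply_3p(
            rng, cfg, hairpin, mature, canon, "del3p" if category == "del3p" else "add3p"
        )
        return seq, 0, off3, tail
    if category == "mixed":
        # combine a 5' change with a 3' change (the common mixed form,
        # e.g. a 5' deletion plus a short 3' addition)
        kind5 = "del5p" if rng.random() < 0.5 else "add5p"
        kind3 = "del3p" if rng.random() < 0.5 else "add3p"
        off5, core = _apply_5p(rng, cfg, mature, hairpin, kind5)
        off3, tail, seq = _apply_3p(rng, cfg, hairpin, mature, core, kind3)
        return seq, off5, off3, tail
    raise ValueError(f"unknown category {category!r}")


def _seq_error(
    rng: np.random.Generator, seq: str, rate: float
) -> tuple[str, bool]:
    if rate <= 0:
        return seq, False
    flips = rng.random(len(seq)) < rate
    if not flips.any():
        return seq, False
    chars = list(seq)
    for pos in np.flatnonzero(flips):
        alternatives = [b for b in BASES if b != chars[pos]]
        chars[pos] = alternatives[int(rng.integers(0, 3))]
    return "".join(chars), True


def _mature_weights(
    rng: np.random.Generator, ref: ReferenceSet, sigma: float
) -> np.ndarray:
    w = np.exp(rng.normal(0.0, sigma, size=len(ref.matures)))
    return w / w.sum()


def simulate_reads(
    ref: ReferenceSet, config: SimConfig
) -> Iterator[tuple[str, str, TruthRecord]]:
    """Yield (read_id, sequence, truth) for one library."""
    rng = np.random.default_rng(config.rng_seed)
    weights = _mature_weights(rng, ref, config.abundance_sigma)
    cats = sorted(config.category_proportions)
    cat_p = np.array([config.category_proportions[c] for c in cats])
    cat_p = cat_p / cat_p.sum()
    mature_idx = rng.choice(len(ref.matures), size=config.n_reads, p=weights)
    cat_idx = rng.choice(len(cats), size=config.n_reads, p=cat_p)
    for i in range(config.n_reads):
        mature = ref.matures[int(mature_idx[i])]
        hairpin = ref.hairpins[mature.hairpin_id]
        requested = cats[int(cat_idx[i])]
        seq, off5, off3, tail = synthesize_variant(
            rng, config, mature, hairpin, requested
        )
        # the realized category can differ from the requested one when
        # geometry clips an edit to nothing; truth reflects what was made
        n_changes = (off5 != 0) + (off3 != 0) + (requested == "substitution")
        if n_changes == 0:
            realized = "canonical" if requested != "substitution" else "substitution"
        elif n_changes >= 2:
            realized = "mixed"
        elif requested == "substitution":
            realized = "substitution"
        elif off5 > 0:
            realized = "del5p"
        elif off5 < 0:
            realized = "add5p"
        elif off3 < 0:
            realized = "del3p"
        else:
            realized = "add3p"
        seq, erred = _seq_error(rng, seq, config.sequencing_error_rate)
        read_id = f"sim-{i + 1:08d}"
        yield read_id, seq, TruthRecord(
            read_id=read_id,
            mature_name=mature.name,
            category=realized,
            offset5=off5,
            offset3=off3,
            tail=tail,
            had_seq_error=erred,
        )


def _open_text(path: Path, mode: str = "wt"):
    return gzip.open(path, mode) if path.suffix == ".gz" else open(path, mode[0])


def simulate_library(
    ref: ReferenceSet,
    config: SimConfig,
    fastq_path: str | Path,
    truth_path: str | Path | None = None,
) -> pd.DataFrame:
    """Write a FASTQ library (+ truth TSV); returns the truth table."""
    fastq_path = Path(fastq_path)
    truths: list[TruthRecord] = []
    with _open_text(fastq_path) as fh:
        for read_id, seq, truth in simulate_reads(ref, config):
            fh.write(f"@{read_id}\n{seq}\n+\n{_QUAL_CHAR * len(seq)}\n")
            truths.append(truth)
    truth_df = pd.DataFrame([asdict(t) for t in truths])
    if truth_path is not None:
        truth_df.to_csv(truth_path, sep="\t", index=False)
    return truth_df


# ---------------------------------------------------------------------------
# RIP experiment simulation
# ---------------------------------------------------------------------------

RIP_LIBRARIES = [
    ("control", "input"),
    ("control", "RIP"),
    ("IL1B", "input"),
    ("IL1B", "RIP"),
]


def build_variant_pool(
    ref: ReferenceSet, config: SimConfig, variants_per_mature: int = 4
) -> pd.DataFrame:
    """Deterministic catalogue of variant sequences with baseline weights.

    Each mature contributes its canonical form plus sampled variants;
    the mature's abundance mass is split across its variants by the
    category proportions.  Columns: the VariantKey fields, ``sequence``
    and ``weight`` (normalized over the pool).
    """
    rng = np.random.default_rng(config.rng_seed)
    weights = _mature_weights(rng, ref, config.abundance_sigma)
    cats = [c for c in sorted(config.category_proportions) if c != "canonical"]
    cat_p = np.array([config.category_proportions[c] for c in cats], dtype=float)
    cat_p /= cat_p.sum()
    rows: dict[tuple, dict] = {}
    seen_seqs: set[str] = set()
    for mi, mature in enumerate(ref.matures):
        hairpin = ref.hairpins[mature.hairpin_id]
        p_canon = config.category_proportions.get("canonical", 0.0)
        entries: list[tuple[str, str, int, int, str]] = [
            ("canonical", mature.canonical_sequence, 0, 0, "")
        ]
        masses = [p_canon]
        n_var = max(variants_per_mature - 1, 0)
        for _ in range(n_var):
            category = cats[int(rng.choice(len(cats), p=cat_p))]
            seq, off5, off3, tail = synthesize_variant(
                rng, config, mature, hairpin, category
            )
            if seq in seen_seqs or seq == mature.canonical_sequence:
                continue
            entries.append((category, seq, off5, off3, tail))
            masses.append(config.category_proportions.get(category, 0.01))
        mass = np.array(masses, dtype=float)
        mass = mass / mass.sum() * weights[mi]
        for (category, seq, off5, off3, tail), w in zip(entries, mass):
            subs = ""
            if category == "substitution" or (
                category == "mixed" and off5 == 0 and off3 == 0
            ):
                subs = _encode_subs_against(mature.canonical_sequence, seq)
            key = (mature.name, off5, off3, subs, tail)
            if key in rows:
                rows[key]["weight"] += float(w)
                continue
            seen_seqs.add(seq)
            rows[key] = {
                "mature": mature.name,
                "offset5": off5,
                "offset3": off3,
                "substitutions": subs,
                "tail": tail,
                "sequence": seq,
                "weight": float(w),
            }
    pool = pd.DataFrame(list(rows.values()))
    pool["weight"] /= pool["weight"].sum()
    return pool


def _encode_subs_against(canonical: str, seq: str) -> str:
    if len(canonical) != len(seq):
        return ""
    return ";".join(
        f"{i}:{a}>{b}" for i, (a, b) in enumerate(zip(canonical, seq)) if a != b
    )


def simulate_rip_experiment(
    ref: ReferenceSet,
    config: SimConfig,
    spikes: dict[VariantKey, float],
    out_dir: str | Path,
    variants_per_mature: int = 4,
    compress: bool = False,
) -> tuple[dict[tuple[str, str], Path], pd.DataFrame]:
    """Four libraries (control/IL1B x input/RIP) with planted enrichments.

    The IL-1β RIP library samples each spiked variant with its baseline
    weight multiplied by 2**log2FC (then renormalized); the other three
    libraries share the baseline.  Returns ({(condition, fraction):
    fastq path}, truth table with planted fold changes per variant).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pool = build_variant_pool(ref, config, variants_per_mature)
    key_index = {
        VariantKey(r.mature, r.offset5, r.offset3, r.substitutions, r.tail): i
        for i, r in enumerate(pool.itertuples())
    }
    for key in spikes:
        if VariantKey(*key) not in key_index:
            raise KeyError(f"spiked variant not in pool: {key}")
    base_w = pool["weight"].to_numpy().copy()
    rip_w = base_w.copy()
    for key, l2fc in spikes.items():
        rip_w[key_index[VariantKey(*key)]] *= 2.0**l2fc
    rip_w /= rip_w.sum()

    rng = np.random.default_rng(config.rng_seed + 1)  # after pool construction
    paths: dict[tuple[str, str], Path] = {}
    suffix = ".fastq.gz" if compress else ".fastq"
    for condition, fraction in RIP_LIBRARIES:
        w = rip_w if (condition == "IL1B" and fraction == "RIP") else base_w
        counts = rng.multinomial(config.n_reads, w / w.sum())
        path = out_dir / f"{condition}_{fraction}{suffix}"
        paths[(condition, fraction)] = path
        with _open_text(path) as fh:
            idx = 0
            for row, n in zip(pool.itertuples(), counts):
                for _ in range(int(n)):
                    idx += 1
                    fh.write(
                        f"@{condition}-{fraction}-{idx:08d}\n{row.sequence}\n+\n"
                        f"{_QUAL_CHAR * len(row.sequence)}\n"
                    )
    truth = pool.copy()
    truth["log2fc"] = 0.0
    for key, l2fc in spikes.items():
        truth.loc[key_index[VariantKey(*key)], "log2fc"] = l2fc
    truth.to_csv(out_dir / "rip_truth.tsv", sep="\t", index=False)
    with open(out_dir / "sim_config.json", "w") as fh:
        json.dump(asdict(config), fh, indent=2, default=str)
    return paths, truth
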