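"""Count tables and descriptive miRNome statistics.

Variant-level raw counts (fractional when a read multi-maps) are held in
a pandas DataFrame indexed by the variant signature (mature, offset5,
offset3, substitutions, tail) with one column per sample.  CPM
normalization divides by per-sample totals; the descriptive layers on
top reproduce the standard small-RNA summaries: abundance ranking with
cumulative contribution, 5p/3p arm usage at a detection floor, per-miRNA
isomiR category composition, isoform diversity at a read-count floor,
and per-variant two-group Student t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .isomir import (
    AlignmentCandidate,
    IsomiRCall,
    IsomiRCategory,
    classify_candidate,
    encode_substitutions,
)
from .reference import ReferenceSet

KEY_FIELDS = ["mature", "offset5", "offset3", "substitutions", "tail"]

CPM_SCALE = 1e6


class VariantKey(NamedTuple):
    """Signature of a miRNA variant; (m, 0, 0, "", "") is canonical."""

    mature: str
    offset5: int
    offset3: int
    substitutions: str  # canonical "pos:ref>alt;..." encoding
    tail: str

    @property
    def is_canonical(self) -> bool:
        return self.offset5 == 0 and self.offset3 == 0 and not self.substitutions

    @property
    def category(self) -> IsomiRCategory:
        cand = AlignmentCandidate(
            mature_name=self.mature,
            offset5=self.offset5,
            offset3=self.offset3,
            substitutions=tuple(
                (int(p.split(":")[0]), p.split(":")[1][0], p.split(":")[1][2])
                for p in self.substitutions.split(";")
                if p
            ),
            templated_ext3=max(self.offset3, 0) - len(self.tail),
            nta_tail=self.tail,
        )
        return classify_candidate(cand)


def key_of_call(call: IsomiRCall) -> VariantKey:
    c = call.candidate
    return VariantKey(
        mature=c.mature_name,
        offset5=c.offset5,
        offset3=c.offset3,
        substitutions=encode_substitutions(c.substitutions),
        tail=c.nta_tail,
    )


@dataclass
class CountTable:
    """Raw counts (and optionally CPM) per variant x sample."""

    counts: pd.DataFrame  # index: MultiIndex over KEY_FIELDS; columns: samples
    cpm: pd.DataFrame | None = None

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def keys(self) -> list[VariantKey]:
        return [VariantKey(*idx) for idx in self.counts.index]

    def categories(self) -> pd.Series:
        return pd.Series(
            [k.category.value for k in self.keys()], index=self.counts.index
        )

    def require_cpm(self) -> pd.DataFrame:
        if self.cpm is None:
            raise ValueError("table is not CPM-normalized; call normalize_cpm first")
        return self.cpm

    def to_tsv(self, path: str | Path, what: Literal["counts", "cpm"] = "counts") -> None:
        df = self.counts if what == "counts" else self.require_cpm()
        df.to_csv(path, sep="\t", float_format="%.6g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountTable":
        df = pd.read_csv(path, sep="\t", keep_default_na=False)
        df["offset5"] = df["offset5"].astype(int)
        df["offset3"] = df["offset3"].astype(int)
        df = df.set_index(KEY_FIELDS)
        return cls(counts=df.astype(float))


def build_count_table(calls: Iterable[IsomiRCall]) -> CountTable:
    """Aggregate calls into a variant x sample raw count matrix.

    Each call contributes ``read.count * assigned_fraction``; summing a
    sample column therefore recovers the number of assigned reads.
    """
    acc: dict[tuple, dict[str, float]] = {}
    for call in calls:
        key = tuple(key_of_call(call))
        row = acc.setdefault(key, {})
        sample = call.read.sample_id
        row[sample] = row.get(sample, 0.0) + call.read.count * call.assigned_fraction
    if not acc:
        idx = pd.MultiIndex.from_arrays([[] for _ in KEY_FIELDS], names=KEY_FIELDS)
        return CountTable(counts=pd.DataFrame(index=idx))
    df = pd.DataFrame.from_dict(acc, orient="index").fillna(0.0)
    df.index = pd.MultiIndex.from_tuples(df.index, names=KEY_FIELDS)
    df = df.sort_index()
    df = df[sorted(df.columns)]
    return CountTable(counts=df)


def normalize_cpm(table: CountTable) -> CountTable:
    """Counts-per-million: count / sample total * 1e6."""
    totals = table.counts.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"zero-total sample(s): {', '.join(map(str, zero.index))}")
    return CountTable(counts=table.counts, cpm=table.counts / totals * CPM_SCALE)


def rank_cumulative(
    table: CountTable, level: Literal["mature", "variant"] = "mature"
) -> pd.DataFrame:
    """Abundance ranking with cumulative % contribution.

    At the mature level, variant CPM is summed per mature and averaged
    across samples before ranking (pooling raw counts instead is a
    matter of re-running on a summed table).
    """
    cpm = table.require_cpm()
    if level == "mature":
        vals = cpm.groupby(level="mature").sum().mean(axis=1)
        vals.index.name = "name"
    else:
        vals = cpm.mean(axis=1)
        vals.index = [
            f"{k.mature}|{k.offset5}|{k.offset3}|{k.substitutions}|{k.tail}"
            for k in table.keys()
        ]
        vals.index.name = "name"
    vals = vals.sort_values(ascending=False, kind="stable")
    pct = vals / vals.sum() * 100.0
    out = pd.DataFrame({"pct": pct, "cumulative_pct": pct.cumsum()})
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    return out.reset_index()


def arm_usage(
    table: CountTable, ref: ReferenceSet, min_cpm: float = 1.0
) -> pd.DataFrame:
    """Per-precursor arm expression call at a mean-CPM detection floor.

    ``both`` when the 5p and 3p arms both reach min_cpm mean CPM,
    ``5p-only``/``3p-only`` when exactly one does, ``none`` otherwise.
    """
    cpm = table.require_cpm()
    mature_cpm = cpm.groupby(level="mature").sum().mean(axis=1)
    arm_by_mature = {m.name: (m.hairpin_id, m.arm) for m in ref.matures}
    per_prec: dict[str, dict[str, float]] = {
        hid: {"5p": 0.0, "3p": 0.0} for hid in ref.hairpins
    }
    for name, value in mature_cpm.items():
        if name not in arm_by_mature:
            continue
        hid, arm = arm_by_mature[name]
        per_prec[hid][arm] += float(value)
    rows = []
    for hid in sorted(per_prec):
        if not ref.matures_of(hid):
            continue
        c5, c3 = per_prec[hid]["5p"], per_prec[hid]["3p"]
        has5, has3 = c5 >= min_cpm, c3 >= min_cpm
        usage = (
            "both"
            if has5 and has3
            else "5p-only"
            if has5
            else "3p-only"
            if has3
            else "none"
        )
        rows.append(
            {"precursor_id": hid, "usage": usage, "cpm_5p": c5, "cpm_3p": c3}
        )
    return pd.DataFrame(rows, columns=["precursor_id", "usage", "cpm_5p", "cpm_3p"])


CATEGORY_ORDER = [c.value for c in IsomiRCategory]


def isomir_composition(
    table: CountTable,
) -> tuple[pd.DataFrame, pd.Series, dict[str, float]]:
    """Category composition: per-mature fractions, global fractions, summaries.

    Returns (per_mature, global_fractions, summary) where summary holds
    the derived headline quantities: % canonical vs % any-variant of all
    counts, and the % of isomiR (non-canonical) counts carrying any 3'
    change.
    """
    keys = table.keys()
    df = pd.DataFrame(
        {
            "count": table.counts.sum(axis=1).to_numpy(),
            "category": [k.category.value for k in keys],
            "mature": [k.mature for k in keys],
            "offset3": [k.offset3 for k in keys],
        }
    )

    by_cat = df.groupby("category")["count"].sum()
    by_cat = by_cat.reindex(CATEGORY_ORDER, fill_value=0.0)
    total = by_cat.sum()
    global_frac = by_cat / total if total > 0 else by_cat

    pivot = df.pivot_table(
        index="mature", columns="category", values="count", aggfunc="sum", fill_value=0.0
    )
    pivot = pivot.reindex(columns=CATEGORY_ORDER, fill_value=0.0)
    per_mature = pivot.div(pivot.sum(axis=1), axis=0)

    variant_mask = df["category"] != IsomiRCategory.CANONICAL.value
    variant_total = df.loc[variant_mask, "count"].sum()
    has_3p = df["category"].isin(
        [IsomiRCategory.DEL3P.value, IsomiRCategory.ADD3P.value]
    ) | ((df["category"] == IsomiRCategory.MIXED.value) & (df["offset3"] != 0))
    summary = {
        "pct_canonical": float(global_frac[IsomiRCategory.CANONICAL.value] * 100),
        "pct_variant": float((1 - global_frac[IsomiRCategory.CANONICAL.value]) * 100),
        "pct_isomir_with_3p_change": float(
            df.loc[variant_mask & has_3p, "count"].sum() / variant_total * 100
        )
        if variant_total > 0
        else 0.0,
    }
    return per_mature, global_frac, summary


def isoform_diversity(table: CountTable, min_reads: float = 100) -> pd.Series:
    """Distinct variants per mature with total raw reads >= min_reads."""
    totals = table.counts.sum(axis=1)
    keep = totals[totals >= min_reads]
    if keep.empty:
        return pd.Series(dtype=int, name="n_isoforms")
    out = keep.groupby(level="mature").size().astype(int)
    out.name = "n_isoforms"
    return out.sort_values(ascending=False, kind="stable")


def group_ttest(
    table: CountTable, group_a: Sequence[str], group_b: Sequence[str]
) -> pd.DataFrame:
    """Two-tailed Student's (pooled-variance) t-test per variant on CPM.

    Zero-pooled-variance rows are flagged ``degenerate``: equal means
    give t=0, p=1; different means are reported as p=0 (infinitely
    concentrated groups), never silently dropped.
    """
    for name, grp in (("a", group_a), ("b", group_b)):
        if len(grp) < 2:
            raise ValueError(f"group {name} needs >= 2 samples, got {len(grp)}")
    cpm = table.require_cpm()
    a = cpm[list(group_a)].to_numpy(float)
    b = cpm[list(group_b)].to_numpy(float)
    import warnings

    with warnings.catch_warnings():
        # constant rows trigger a precision-loss warning; they are
        # re-resolved explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=True)
    var_a = a.var(axis=1, ddof=1)
    var_b = b.var(axis=1, ddof=1)
    degenerate = (var_a == 0) & (var_b == 0)
    mean_diff = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(invalid="ignore"):
        t = np.where(
            degenerate,
            np.where(mean_diff == 0, 0.0, np.inf * np.sign(mean_diff)),
            t,
        )
    p = np.where(degenerate, np.where(mean_diff == 0, 1.0, 0.0), p)
    return pd.DataFrame(
        {
            "mean_a": a.mean(axis=1),
            "mean_b": b.mean(axis=1),
            "t": t,
            "p": p,
            "degenerate": degenerate,
        },
        index=cpm.index,
    )
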