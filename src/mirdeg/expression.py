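"""Expression quantification across conditions: miRNA abundance matrices,
fold changes with significance stars, 2^-ddCt qPCR quantification, and
miRNA-down / target-up concordance reporting.

Differential testing uses a two-sided Welch t-test on log2(value + pseudo)
per feature, with no multiple-testing correction (the handful of planted
features does not warrant one; documented, config-exposed). Stars follow
the convention "**" for p <= 0.01 and "***" for p <= 0.001.

RPM values are compositional: when every miRNA in a small library moves the
same direction (the drought design), total-count normalisation absorbs part
of the shift. ``differential(..., values="raw")`` operates on raw counts,
which are comparable across libraries sequenced at the same nominal depth
and recover planted effects without that bias.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._seq import normalize
from .srna import SmallRnaTag

PSEUDO_DEFAULT = 0.25


@dataclass(frozen=True)
class ExpressionMatrix:
    """feature x library values with the condition/replicate design."""

    rpm: pd.DataFrame  # features x libraries
    raw: pd.DataFrame
    meta: pd.DataFrame  # index: library id; columns: condition, replicate

    def __post_init__(self) -> None:
        if (self.rpm.values < 0).any():
            raise ValueError("expression values must be >= 0")
        missing = set(self.rpm.columns) - set(self.meta.index)
        if missing:
            raise ValueError(f"libraries without metadata: {sorted(missing)}")

    def libraries(self, condition: str) -> list[str]:
        return list(self.meta.index[self.meta["condition"] == condition])


def build_matrix(
    tag_sets: Mapping[str, Sequence[SmallRnaTag]],
    features: Mapping[str, str],
    meta: pd.DataFrame,
    kind: str = "mirna",
) -> ExpressionMatrix:
    """Quantify features across libraries of collapsed tags.

    For ``kind="mirna"`` a feature's value is the summed RPM (and raw count)
    of tags exactly matching its mature sequence; for ``kind="transcript"``
    tags matching anywhere within the feature sequence are summed. Features
    absent from a library score 0. Duplicate library ids or libraries
    without metadata raise.
    """
    if meta.index.has_duplicates:
        raise ValueError("duplicate library ids in metadata")
    feats = {fid: normalize(seq) for fid, seq in features.items()}
    lib_ids = list(tag_sets)
    if len(set(lib_ids)) != len(lib_ids):
        raise ValueError("duplicate library ids")
    rpm = pd.DataFrame(0.0, index=sorted(feats), columns=lib_ids)
    raw = pd.DataFrame(0, index=sorted(feats), columns=lib_ids)
    for lib, tags in tag_sets.items():
        for fid, fseq in feats.items():
            if kind == "mirna":
                sel = [t for t in tags if t.sequence == fseq]
            elif kind == "transcript":
                sel = [t for t in tags if t.sequence in fseq]
            else:
                raise ValueError(f"unknown kind {kind!r}")
            rpm.loc[fid, lib] = sum(t.rpm for t in sel)
            raw.loc[fid, lib] = sum(t.raw_count for t in sel)
    return ExpressionMatrix(rpm, raw, meta)


@dataclass(frozen=True)
class DiffResult:
    feature: str
    cond_a: str
    cond_b: str
    log2fc: float
    p_value: float
    stars: str


def _stars(p: float) -> str:
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    return ""


def differential(
    matrix: ExpressionMatrix,
    cond_a: str,
    cond_b: str,
    pseudo: float = PSEUDO_DEFAULT,
    values: str = "rpm",
) -> pd.DataFrame:
    """Per-feature log2 fold change (B - A) with Welch t-test p-values.

    log2FC = mean(log2(v_B + pseudo)) - mean(log2(v_A + pseudo)); p from a
    two-sided Welch t-test on the log2 values. Groups that are identical
    constants give log2FC = 0, p = 1. No multiple-testing correction is
    applied. Requires >= 2 replicates per condition.
    """
    vals = getattr(matrix, values)
    libs_a, libs_b = matrix.libraries(cond_a), matrix.libraries(cond_b)
    if len(libs_a) < 2 or len(libs_b) < 2:
        raise ValueError("need >= 2 replicates per condition")
    a = np.log2(vals[libs_a].to_numpy(dtype=float) + pseudo)
    b = np.log2(vals[libs_b].to_numpy(dtype=float) + pseudo)
    log2fc = b.mean(axis=1) - a.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(b, a, axis=1, equal_var=False)
    p = np.asarray(p, dtype=float)
    degenerate = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    p[degenerate & (log2fc == 0)] = 1.0
    p[degenerate & (log2fc != 0)] = 0.0
    rows = pd.DataFrame(
        {
            "feature": vals.index,
            "cond_a": cond_a,
            "cond_b": cond_b,
            "log2fc": log2fc,
            "p_value": p,
        }
    )
    rows["stars"] = [_stars(x) for x in rows["p_value"]]
    return rows


def ddct(
    records: pd.DataFrame,
    target_gene: str,
    reference_gene: str,
    calibrator: str,
) -> pd.Series:
    """Relative qPCR quantification: fold change per condition by 2^-ddCt.

    dCt = Ct(target) - Ct(reference) per sample; ddCt = mean dCt(condition)
    - mean dCt(calibrator); fold = 2^-ddCt. The reference gene must be
    measured in every sample containing the target.
    """
    t = records[records["gene"] == target_gene]
    r = records[records["gene"] == reference_gene]
    if t.empty:
        raise ValueError(f"no records for target gene {target_gene!r}")
    merged = t.merge(
        r[["condition", "replicate", "ct"]],
        on=["condition", "replicate"],
        suffixes=("", "_ref"),
        how="left",
    )
    if merged["ct_ref"].isna().any():
        raise ValueError("reference gene missing in at least one sample")
    if not np.isfinite(merged["ct"]).all() or (merged["ct"] <= 0).any():
        raise ValueError("Ct values must be finite and > 0")
    merged["dct"] = merged["ct"] - merged["ct_ref"]
    mean_dct = merged.groupby("condition", sort=False)["dct"].mean()
    if calibrator not in mean_dct.index:
        raise ValueError(f"calibrator condition {calibrator!r} not measured")
    ddct_vals = mean_dct - mean_dct[calibrator]
    return (2.0 ** (-ddct_vals)).rename("fold_change")


def concordance(
    mirna_diffs: pd.DataFrame,
    target_diffs: pd.DataFrame,
    links: Sequence[tuple[str, str]],
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-link miRNA/target regulation concordance.

    A link (miRNA, transcript) is concordant when the miRNA and its target
    move in opposite directions (miRNA down & target up, or the reverse).
    Links with a missing differential result are skipped and counted.
    """
    m = mirna_diffs.set_index("feature")["log2fc"]
    t = target_diffs.set_index("feature")["log2fc"]
    rows, skipped = [], 0
    for mid, tid in links:
        if mid not in m.index or tid not in t.index:
            skipped += 1
            continue
        mfc, tfc = float(m[mid]), float(t[tid])
        rows.append(
            dict(
                mirna=mid,
                transcript=tid,
                mirna_log2fc=mfc,
                target_log2fc=tfc,
                concordant=(mfc < 0 < tfc) or (tfc < 0 < mfc),
            )
        )
    table = pd.DataFrame(rows, columns=["mirna", "transcript", "mirna_log2fc", "target_log2fc", "concordant"])
    summary = {
        "n_links": len(links),
        "n_evaluated": len(table),
        "n_concordant": int(table["concordant"].sum()) if not table.empty else 0,
        "n_skipped": skipped,
    }
    return table, summary
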