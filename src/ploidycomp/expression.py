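"""Cross-ploidy expression comparison of syntenic gene pairs.

A pair is *expressed* if either gene reaches the TPM threshold (default 1)
in at least one tissue. Hexaploid TPM values are rescaled by a
median-of-ratios normalization factor — the median over expressed pairs,
pooled across tissues, of (diploid TPM + eps) / (hexaploid TPM + eps) — to
absorb the genome-wide proportionate reduction of hexaploid expression
(~40% of diploid, hence a factor near 1/0.4; the original study used the
fixed value 1.7604, available via ``method="fixed"``). After rescaling, a
pair is a DEG in a tissue if the ratio crosses the 4-fold threshold in
either direction (inclusive); expressed pairs that are DEG in no tissue are
the "proportionately reduced" (balanced) class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: pseudocount added to numerator and denominator of every TPM ratio
EPSILON = 0.01

#: the original study's fixed cross-ploidy normalization factor
DEFAULT_FIXED_FACTOR = 1.7604

CLASS_BALANCED = "balanced"
CLASS_UP_HEX = "deg_up_hexaploid"
CLASS_UP_DIP = "deg_up_diploid"
CLASS_NOT_EXPRESSED = "not_expressed"


@dataclass(frozen=True)
class NormalizationResult:
    factor: float
    method: str
    n_pairs_used: int

    def __post_init__(self) -> None:
        if not self.factor > 0:
            raise ValueError("normalization factor must be positive")


def aggregate_replicates(
    tpm: pd.DataFrame, design: Mapping[str, str]
) -> pd.DataFrame:
    """Arithmetic mean of replicate TPM columns per tissue.

    ``design`` maps sample column name -> tissue. Missing columns and NaNs
    are errors, never silently propagated.
    """
    missing = [s for s in design if s not in tpm.columns]
    if missing:
        raise KeyError(f"sample columns missing from TPM matrix: {missing}")
    sub = tpm[list(design)]
    if sub.isna().any().any():
        raise ValueError("NaN TPM values in input matrix")
    tissues = pd.Series(design)
    return sub.T.groupby(tissues).mean().T


def _pair_tpm(
    pairs: pd.DataFrame, tpm_diploid: pd.DataFrame, tpm_hexaploid: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Align per-tissue TPM matrices to the pair table; returns (dip, hex,
    tissues) arrays of shape (n_pairs, n_tissues)."""
    tissues = [t for t in tpm_diploid.columns if t in tpm_hexaploid.columns]
    if not tissues:
        raise ValueError("no shared tissue columns between genomes")
    d = tpm_diploid.loc[pairs["diploid_gene_id"], tissues].to_numpy(float)
    h = tpm_hexaploid.loc[pairs["hexaploid_gene_id"], tissues].to_numpy(float)
    return d, h, tissues


def flag_expressed(
    pairs: pd.DataFrame,
    tpm_diploid: pd.DataFrame,
    tpm_hexaploid: pd.DataFrame,
    threshold: float = 1.0,
) -> pd.Series:
    """Expressed = TPM >= threshold for either gene in any tissue (inclusive)."""
    d, h, _ = _pair_tpm(pairs, tpm_diploid, tpm_hexaploid)
    expressed = (d.max(axis=1) >= threshold) | (h.max(axis=1) >= threshold)
    return pd.Series(expressed, index=pairs.index, name="expressed")


def compute_normalization_factor(
    pairs: pd.DataFrame,
    tpm_diploid: pd.DataFrame,
    tpm_hexaploid: pd.DataFrame,
    expressed: pd.Series,
    method: str = "median_ratio",
    fixed_factor: float = DEFAULT_FIXED_FACTOR,
    eps: float = EPSILON,
) -> NormalizationResult:
    """Median-of-ratios cross-ploidy factor, or the fixed published constant.

    median_ratio: median over expressed pairs, pooled across tissues, of
    (diploid TPM + eps)/(hexaploid TPM + eps).
    """
    if method == "fixed":
        return NormalizationResult(fixed_factor, "fixed", 0)
    if method != "median_ratio":
        raise ValueError(f"unknown normalization method {method!r}")
    d, h, _ = _pair_tpm(pairs, tpm_diploid, tpm_hexaploid)
    mask = expressed.to_numpy(bool)
    if mask.sum() == 0:
        raise ValueError("no expressed pairs to normalize on")
    if mask.sum() < 10:
        raise ValueError("median_ratio needs >= 10 expressed pairs")
    ratios = (d[mask] + eps) / (h[mask] + eps)
    return NormalizationResult(float(np.median(ratios)), "median_ratio", int(mask.sum()))


def classify_pairs(
    pairs: pd.DataFrame,
    tpm_diploid: pd.DataFrame,
    tpm_hexaploid: pd.DataFrame,
    expressed: pd.Series,
    factor: float,
    fold: float = 4.0,
    eps: float = EPSILON,
) -> pd.DataFrame:
    """Per-tissue and overall class for every pair.

    Per tissue: r = (factor x hexaploid TPM + eps)/(diploid TPM + eps);
    r >= fold -> deg_up_hexaploid, r <= 1/fold -> deg_up_diploid (both
    inclusive), else balanced. Overall: DEG if DEG in any tissue; expressed
    non-DEG pairs are the proportionately reduced ("balanced") class.
    """
    if fold <= 1:
        raise ValueError("fold threshold must exceed 1")
    if not factor > 0:
        raise ValueError("factor must be positive")
    d, h, tissues = _pair_tpm(pairs, tpm_diploid, tpm_hexaploid)
    r = (factor * h + eps) / (d + eps)
    per_tissue = np.where(
        r >= fold, CLASS_UP_HEX, np.where(r <= 1.0 / fold, CLASS_UP_DIP, CLASS_BALANCED)
    ).astype(object)
    mask = expressed.to_numpy(bool)
    per_tissue[~mask, :] = CLASS_NOT_EXPRESSED

    out = pairs[["diploid_gene_id", "hexaploid_gene_id"]].copy()
    out["expressed"] = mask
    for j, t in enumerate(tissues):
        out[f"class_{t}"] = per_tissue[:, j]
    is_deg = np.isin(per_tissue, [CLASS_UP_HEX, CLASS_UP_DIP]).any(axis=1)
    overall = np.where(~mask, CLASS_NOT_EXPRESSED,
                       np.where(is_deg, "deg", CLASS_BALANCED))
    out["overall_class"] = overall
    # per-pair pooled ratio of raw (unscaled) TPMs, for reporting
    out["mean_raw_ratio"] = ((h + eps) / (d + eps)).mean(axis=1)
    return out


def conserved_degs(
    deg_sets: Mapping[str, Mapping[str, str]]
) -> set[str]:
    """Pairs DEG in the same direction versus every accession.

    ``deg_sets`` maps accession name -> {pair/gene id -> direction}, with
    direction one of deg_up_hexaploid / deg_up_diploid. Requires >= 2
    accession comparisons.
    """
    if len(deg_sets) < 2:
        raise ValueError("need >= 2 accession comparisons")
    per_acc = list(deg_sets.values())
    common = set(per_acc[0])
    for s in per_acc[1:]:
        common &= set(s)
    return {g for g in common if len({s[g] for s in per_acc}) == 1}


def stage_specific_summary(classes: pd.DataFrame) -> pd.DataFrame:
    """Per-tissue tallies of DEGs up in each genome.

    Expects the output of :func:`classify_pairs`; returns a tissue-indexed
    frame with columns deg_up_hexaploid, deg_up_diploid, deg_total.
    """
    tissue_cols = [c for c in classes.columns if c.startswith("class_")]
    rows = {}
    for col in tissue_cols:
        tissue = col[len("class_"):]
        up_h = int((classes[col] == CLASS_UP_HEX).sum())
        up_d = int((classes[col] == CLASS_UP_DIP).sum())
        rows[tissue] = {"deg_up_hexaploid": up_h, "deg_up_diploid": up_d,
                        "deg_total": up_h + up_d}
    return pd.DataFrame.from_dict(rows, orient="index")


def deg_directions(classes: pd.DataFrame, tissue: str, key: str = "hexaploid_gene_id") -> dict[str, str]:
    """DEG pairs and directions in one tissue, keyed by ``key`` gene id —
    the per-accession input to :func:`conserved_degs`."""
    col = f"class_{tissue}"
    if col not in classes.columns:
        raise KeyError(f"no such tissue column {col!r}")
    sel = classes[classes[col].isin([CLASS_UP_HEX, CLASS_UP_DIP])]
    return dict(zip(sel[key], sel[col]))
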