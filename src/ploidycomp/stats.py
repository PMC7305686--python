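"""Cross-modality statistics: gene-set overlap tests, peak-length ANOVA,
binned positional correlation, pairwise sequence identity and promoter
k-mer enrichment."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class OverlapStat:
    n_universe: int
    n_set_a: int
    n_set_b: int
    n_overlap: int
    p_hyper: float

    def __post_init__(self) -> None:
        if not (self.n_overlap <= min(self.n_set_a, self.n_set_b) <= self.n_universe):
            raise ValueError("inconsistent overlap counts")


def hypergeometric_overlap(
    universe: set[str] | Sequence[str],
    set_a: set[str] | Sequence[str],
    set_b: set[str] | Sequence[str],
) -> OverlapStat:
    """Upper-tail hypergeometric p-value of the observed overlap |A & B|
    among draws of |B| from the universe."""
    u, a, b = set(universe), set(set_a), set(set_b)
    if not (a <= u and b <= u):
        raise ValueError("sets must be subsets of the universe")
    k = len(a & b)
    p = float(sps.hypergeom.sf(k - 1, len(u), len(a), len(b)))
    return OverlapStat(len(u), len(a), len(b), k, p)


@dataclass(frozen=True)
class AnovaResult:
    f: float
    df_between: int
    df_within: int
    p: float


def peak_length_anova(groups: Mapping[str, Sequence[float]]) -> AnovaResult:
    """One-way fixed-effects ANOVA on raw lengths across named groups."""
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if any(a.size == 0 for a in arrays):
        raise ValueError("empty group")
    f, p = sps.f_oneway(*arrays)
    df1 = len(arrays) - 1
    df2 = sum(a.size for a in arrays) - len(arrays)
    return AnovaResult(float(f), df1, df2, float(p))


@dataclass(frozen=True)
class BinnedCorrelation:
    rho: float
    p: float
    n_bins: int
    defined: bool  # False when bin means are constant (rho undefined)


def binned_position_correlation(
    positions: Sequence[float],
    values: Sequence[float],
    bin_size: float = 8e6,
) -> BinnedCorrelation:
    """Spearman correlation between positional bin index and the bin mean of
    a per-gene value (e.g. pair sequence similarity), averaging ties.

    Positions are binned at ``bin_size`` bp (default 8 Mb). Constant bin
    means make the rank correlation undefined; flagged rather than raised.
    """
    pos = np.asarray(positions, dtype=float)
    val = np.asarray(values, dtype=float)
    if pos.size != val.size or pos.size == 0:
        raise ValueError("positions and values must be equal-length, non-empty")
    idx = np.floor(pos / bin_size).astype(int)
    frame = pd.DataFrame({"bin": idx, "value": val})
    means = frame.groupby("bin")["value"].mean().sort_index()
    if means.size < 2 or np.allclose(means, means.iloc[0]):
        return BinnedCorrelation(float("nan"), float("nan"), int(means.size), False)
    rho, p = sps.spearmanr(means.index.to_numpy(), means.to_numpy())
    return BinnedCorrelation(float(rho), float(p), int(means.size), True)


def pairwise_identity(
    seq_a: str,
    seq_b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> float:
    """Percent identity from a global alignment (matches / alignment columns
    x 100); symmetric in its arguments."""
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    aln = aligner.align(seq_a.upper(), seq_b.upper())[0]
    a, b = str(aln[0]), str(aln[1])
    matches = sum(x == y and x != "-" for x, y in zip(a, b))
    return 100.0 * matches / len(a)


def kmer_promoter_enrichment(
    target_promoters: Sequence[str],
    background_promoters: Sequence[str],
    k: int = 6,
) -> pd.DataFrame:
    """Presence/absence k-mer enrichment in target vs background promoters.

    For each k-mer seen in any promoter, counts the promoters containing it
    and tests target enrichment with an upper-tail hypergeometric
    (universe = all promoters, draws = targets); BH-adjusted across k-mers.
    Columns: kmer, n_target, n_background, p, q (sorted by q).
    """
    from statsmodels.stats.multitest import multipletests

    targets = [s.upper() for s in target_promoters]
    background = [s.upper() for s in background_promoters]
    if not targets or not background:
        raise ValueError("need non-empty target and background sets")

    def _kmers(seq: str) -> set[str]:
        return {seq[i : i + k] for i in range(len(seq) - k + 1)}

    tgt_sets = [_kmers(s) for s in targets]
    bg_sets = [_kmers(s) for s in background]
    all_kmers = sorted(set().union(*tgt_sets, *bg_sets))
    n_t, n_b = len(targets), len(background)
    n_u = n_t + n_b
    rows = []
    for km in all_kmers:
        kt = sum(km in s for s in tgt_sets)
        kb = sum(km in s for s in bg_sets)
        p = float(sps.hypergeom.sf(kt - 1, n_u, kt + kb, n_t))
        rows.append({"kmer": km, "n_target": kt, "n_background": kb, "p": p})
    table = pd.DataFrame(rows)
    table["q"] = multipletests(table["p"], method="fdr_bh")[1]
    return table.sort_values(["q", "p", "kmer"]).reset_index(drop=True)
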