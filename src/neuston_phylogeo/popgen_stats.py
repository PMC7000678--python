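"""Clade-level haplotype diversity statistics and composition tests.

Implements the descriptive population-genetic layer of the pipeline:

* haplotype collapsing over the analyzed sites (after complete deletion),
* haplotype diversity ``Hd`` with the unbiased n/(n-1) correction,
* ``K``, the mean number of pairwise nucleotide differences, and its
  pooled two-clade variant ``Kt``,
* uncorrected p-distance matrices under pairwise deletion, and
* a per-sequence base-composition heterogeneity chi-square test against
  the pooled composition.

``Hd`` uses the small-sample correction so a sample in which every
sequence is a distinct haplotype scores exactly 1.0 for any n >= 2; the
uncorrected form cannot reach 1.  ``K`` is reported as raw difference
counts, unadjusted for multiple hits.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DisjointnessError, InsufficientSampleError
from .io_formats import CANONICAL, SequenceSet, complete_deletion


@dataclass
class HaplotypeTable:
    """Unique haplotypes over the analyzed sites, with member lists."""

    haplotypes: list[tuple[str, str, list[str], int]]  # (hap_id, residues, members, count)
    n: int
    analyzed_sites: int

    @property
    def h(self) -> int:
        return len(self.haplotypes)

    @property
    def counts(self) -> list[int]:
        return [c for _, _, _, c in self.haplotypes]

    @property
    def representatives(self) -> list[str]:
        return [r for _, r, _, _ in self.haplotypes]


@dataclass
class DiversitySummary:
    clade_label: str
    n: int
    h: int
    Hd: float
    K: float
    analyzed_sites: int

    @property
    def pi(self) -> float:
        """Nucleotide diversity convenience value, K / analyzed sites."""
        return self.K / self.analyzed_sites if self.analyzed_sites else float("nan")


@dataclass
class CompositionTestResult:
    sequence_id: str
    observed: dict[str, int]
    statistic: float
    df: int
    p_value: float
    flagged: bool
    p_bonferroni: float = field(default=float("nan"))


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray  # square, symmetric, NaN where no comparable sites
    mode: str = "p-distance"

    def min_offdiagonal(self) -> float:
        n = len(self.ids)
        if n < 2:
            raise InsufficientSampleError("need >= 2 sequences for a minimum distance")
        mask = ~np.eye(n, dtype=bool)
        vals = self.values[mask]
        return float(np.nanmin(vals))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def _subset_sites(aln: SequenceSet, subset, deletion: str) -> SequenceSet:
    sub = aln.subset(list(subset))
    if deletion == "complete":
        return complete_deletion(sub)
    if deletion == "pairwise":
        return sub
    raise ValueError(f"unknown deletion mode {deletion!r}")


def collapse_haplotypes(aln: SequenceSet, subset=None) -> HaplotypeTable:
    """Collapse identical sequences over the surviving analyzed sites.

    Complete deletion is applied to the subset first, so two sequences that
    differ only at a column excluded by a third member's gap collapse into
    one haplotype.  Numbering follows first occurrence.
    """
    ids = list(subset) if subset is not None else aln.ids
    if not ids:
        raise InsufficientSampleError("empty subset")
    analyzed = _subset_sites(aln, ids, "complete")
    groups: dict[str, list[str]] = {}
    order: list[str] = []
    for s in analyzed:
        if s.residues not in groups:
            groups[s.residues] = []
            order.append(s.residues)
        groups[s.residues].append(s.id)
    haps = [
        (f"H{k + 1}", res, groups[res], len(groups[res]))
        for k, res in enumerate(order)
    ]
    return HaplotypeTable(haps, n=len(ids), analyzed_sites=len(analyzed.sequences[0]))


def haplotype_diversity(table: HaplotypeTable) -> float:
    """Unbiased haplotype diversity Hd = n/(n-1) * (1 - sum p_i^2)."""
    n = table.n
    if n < 2:
        raise InsufficientSampleError("Hd requires n >= 2")
    p = np.array(table.counts, dtype=float) / n
    hd = n / (n - 1) * (1.0 - float(np.sum(p**2)))
    return float(min(max(hd, 0.0), 1.0))


def _pairwise_diff_matrix(analyzed: SequenceSet) -> np.ndarray:
    codes = np.array([list(s.residues) for s in analyzed])
    # raw per-site difference counts over the analyzed (gap-free) sites
    n = codes.shape[0]
    d = np.zeros((n, n), dtype=int)
    for i in range(n):
        d[i] = (codes != codes[i]).sum(axis=1)
    return d


def mean_pairwise_differences(aln: SequenceSet, subset=None, deletion: str = "complete") -> float:
    """K: mean count of differing sites over all sequence pairs.

    Under ``complete`` deletion every pair is compared over the same
    gap/ambiguity-free columns; under ``pairwise`` deletion each pair is
    compared over the sites where both members carry an unambiguous base.
    """
    ids = list(subset) if subset is not None else aln.ids
    n = len(ids)
    if n < 2:
        raise InsufficientSampleError("K requires >= 2 sequences")
    if deletion == "complete":
        analyzed = _subset_sites(aln, ids, "complete")
        d = _pairwise_diff_matrix(analyzed)
    elif deletion == "pairwise":
        sub = aln.subset(ids)
        codes = np.array([list(s.residues) for s in sub])
        valid = np.isin(codes, list(CANONICAL))
        d = np.zeros((n, n), dtype=int)
        for i, j in itertools.combinations(range(n), 2):
            both = valid[i] & valid[j]
            d[i, j] = d[j, i] = int((codes[i][both] != codes[j][both]).sum())
    else:
        raise ValueError(f"unknown deletion mode {deletion!r}")
    return float(d[np.triu_indices(n, k=1)].mean())


def pooled_mean_differences(aln: SequenceSet, subset_a, subset_b) -> float:
    """Kt: K over the pooled subset, complete deletion recomputed on the union."""
    sa, sb = list(subset_a), list(subset_b)
    if set(sa) & set(sb):
        raise DisjointnessError("pooled subsets must be disjoint")
    pooled = sa + sb
    if len(pooled) < 2:
        raise InsufficientSampleError("pooled Kt requires >= 2 sequences")
    return mean_pairwise_differences(aln, pooled)


def diversity_summary(aln: SequenceSet, subset, clade_label: str) -> DiversitySummary:
    table = collapse_haplotypes(aln, subset)
    return DiversitySummary(
        clade_label=clade_label,
        n=table.n,
        h=table.h,
        Hd=haplotype_diversity(table),
        K=mean_pairwise_differences(aln, subset),
        analyzed_sites=table.analyzed_sites,
    )


def p_distance_matrix(aln: SequenceSet, subset=None) -> DistanceMatrix:
    """Uncorrected p-distances under pairwise deletion.

    For each pair only sites where both sequences carry an unambiguous
    A/C/G/T are compared; a pair with zero comparable sites gets NaN with
    a warning.
    """
    if not aln.is_alignment:
        raise ValueError("p_distance_matrix requires an alignment")
    ids = list(subset) if subset is not None else aln.ids
    sub = aln.subset(ids)
    codes = np.array([list(s.residues) for s in sub])
    valid = np.isin(codes, list(CANONICAL))
    n = len(ids)
    out = np.zeros((n, n), dtype=float)
    for i, j in itertools.combinations(range(n), 2):
        both = valid[i] & valid[j]
        compared = int(both.sum())
        if compared == 0:
            warnings.warn(f"no comparable sites between {ids[i]!r} and {ids[j]!r}")
            out[i, j] = out[j, i] = np.nan
            continue
        diff = int((codes[i][both] != codes[j][both]).sum())
        out[i, j] = out[j, i] = diff / compared
    return DistanceMatrix(ids, out)


def composition_chisq(aln: SequenceSet, alpha: float = 0.05) -> list[CompositionTestResult]:
    """Base-composition heterogeneity chi-square test per sequence.

    Pooled A/C/G/T frequencies over all sequences define the expectation;
    each sequence is tested against them with df = 3 (reduced if a pooled
    base is absent).  Flagging uses the uncorrected p < alpha screen; a
    Bonferroni-adjusted p-value is carried alongside.
    """
    if len(aln) < 2:
        raise InsufficientSampleError("composition test requires >= 2 sequences")
    bases = "ACGT"
    per_seq = []
    totals = np.zeros(4)
    for s in aln:
        obs = np.array([s.residues.count(b) for b in bases], dtype=float)
        per_seq.append((s.id, obs))
        totals += obs
    grand = totals.sum()
    if grand == 0:
        raise InsufficientSampleError("no unambiguous residues to test")
    pooled = totals / grand
    m = len(per_seq)
    results = []
    for sid, obs in per_seq:
        L = obs.sum()
        expected = pooled * L
        keep = expected > 0
        if not np.all(keep):
            warnings.warn(
                f"pooled frequency zero for some base; df reduced for {sid!r}"
            )
        df = int(keep.sum()) - 1
        if L == 0 or df <= 0:
            stat, p = 0.0, 1.0
            df = max(df, 0)
        else:
            stat = float(np.sum((obs[keep] - expected[keep]) ** 2 / expected[keep]))
            p = float(stats.chi2.sf(stat, df))
        results.append(
            CompositionTestResult(
                sequence_id=sid,
                observed={b: int(o) for b, o in zip(bases, obs)},
                statistic=stat,
                df=df,
                p_value=p,
                flagged=p < alpha,
                p_bonferroni=min(p * m, 1.0),
            )
        )
    return results


def composition_frame(results: list[CompositionTestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "id": r.sequence_id,
                **{f"n_{b}": c for b, c in r.observed.items()},
                "chi2": r.statistic,
                "df": r.df,
                "p_value": r.p_value,
                "p_bonferroni": r.p_bonferroni,
                "flagged": r.flagged,
            }
            for r in results
        ]
    )
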