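"""Acetylation-dynamics analysis.

Compartment-resolved summaries of SILAC ratios corrected for protein
abundance changes, rank-based significance tests, annotation-term
enrichment, corresponding-peptide sanity checks, TMT reporter-based
relative abundance, and the acetyl-CoA pool arithmetic that links
mitochondrial acetylation dynamics to acetyl-CoA concentration.

A site's compartment is taken from its protein's subcellular
localization, counting only proteins localized *exclusively* to one of
mitochondrion, cytoplasm or nucleus so the compartments stay disjoint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ProteinQuant, TmtRecord

TRACKED_COMPARTMENTS = ("mitochondrion", "cytoplasm", "nucleus")


@dataclass
class CompartmentSummary:
    """Median acetylation change for sites in one compartment."""

    compartment: str
    n_sites: int
    median_log2_ratio: float
    median_linear_ratio: float
    p_vs_reference: float | None = None


@dataclass
class AcetylCoAPools:
    """Whole-cell acetyl-CoA measurements across deletion strains.

    ``total_pda1`` lacks the mitochondrial pool (no pyruvate dehydrogenase
    flux), ``total_cit1`` accumulates it (no citrate synthase drain), so
    pool differences against the wild type isolate the mitochondrial pool.
    """

    total_wt: float
    total_pda1: float
    total_cit1: float
    mito_fraction_of_volume: float = 0.015

    def validate(self) -> None:
        if min(self.total_wt, self.total_pda1, self.total_cit1) <= 0:
            raise ValueError("pool totals must be > 0")
        if not (0.0 < self.mito_fraction_of_volume < 1.0):
            raise ValueError("mito_fraction_of_volume must lie in (0, 1)")


@dataclass
class TmtComparison:
    """Relative abundance between treated and control reporter groups."""

    ratio: float
    p_value: float | None
    degenerate: bool = False


def correct_site_ratio(site_ratio: float, protein_ratio: float) -> float:
    """Remove the protein-abundance component from a site's SILAC ratio."""
    if not (site_ratio > 0 and protein_ratio > 0):
        raise ValueError("both ratios must be > 0")
    return site_ratio / protein_ratio


def exclusive_localization(protein: ProteinQuant) -> str | None:
    """The single tracked compartment a protein belongs to, or None.

    Proteins localized to several compartments (or only untracked ones)
    are excluded from compartment comparisons.
    """
    if len(protein.localizations) != 1:
        return None
    (only,) = protein.localizations
    return only if only in TRACKED_COMPARTMENTS else None


def wilcoxon_rank_sum(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided rank-sum p-value for two independent samples.

    Exact enumeration when the smaller sample has <= 8 values and there
    are no ties; otherwise the normal approximation with midranks,
    tie-corrected variance and continuity correction.
    """
    a = list(a)
    b = list(b)
    if not a or not b:
        raise ValueError("both samples must be non-empty")
    no_ties = len(set(a) | set(b)) == len(a) + len(b)
    method = "exact" if (min(len(a), len(b)) <= 8 and no_ties) else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def fisher_enrichment(k: int, n: int, K: int, N: int) -> float:
    """One-sided enrichment tail P(X >= k) under the hypergeometric null.

    ``k`` of ``n`` selected proteins carry the term; ``K`` of ``N``
    background proteins carry it.
    """
    if not (0 <= k <= n <= N and k <= K <= N):
        raise ValueError(f"inconsistent counts k={k}, n={n}, K={K}, N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def term_enrichment(
    selection: Iterable[str],
    background: Iterable[str],
    annotations: Mapping[str, frozenset],
) -> pd.DataFrame:
    """Enrichment of annotation terms in a protein selection vs background.

    Returns a frame with columns term, k, n, K, N, p, p_bh sorted by p.
    The Benjamini-Hochberg column is provided alongside the raw p-values;
    which to report is left to the caller.
    """
    selection = set(selection)
    background = set(background) | selection
    n, N = len(selection), len(background)
    terms = sorted({t for prot in background for t in annotations.get(prot, frozenset())})
    rows = []
    for term in terms:
        with_term = {prot for prot in background if term in annotations.get(prot, frozenset())}
        k = len(with_term & selection)
        K = len(with_term)
        rows.append((term, k, n, K, N, fisher_enrichment(k, n, K, N)))
    df = pd.DataFrame(rows, columns=["term", "k", "n", "K", "N", "p"])
    if len(df):
        df["p_bh"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    else:
        df["p_bh"] = []
    return df.sort_values("p", kind="mergesort").reset_index(drop=True)


def fraction_above(ratios: Sequence[float], fold: float) -> float:
    """Proportion of ratios strictly greater than ``fold``."""
    ratios = list(ratios)
    if not ratios:
        raise ValueError("empty ratio list")
    return sum(1 for r in ratios if r > fold) / len(ratios)


def cp_abundance_check(unmod_ratios: Sequence[float]) -> dict:
    """Summary of corresponding-peptide (unmodified counterpart) ratios.

    If chemical acetylation is partial, the unmodified peptides should be
    essentially unchanged: median near 1 and most ratios within 2-fold.
    """
    ratios = [float(r) for r in unmod_ratios]
    if not ratios:
        raise ValueError("empty ratio list")
    within = sum(1 for r in ratios if 0.5 <= r <= 2.0) / len(ratios)
    return {"median": float(np.median(ratios)), "fraction_within_2fold": within}


def tmt_purity_filter(records: Iterable[TmtRecord], threshold: float = 0.90) -> list:
    """Keep records whose parent-ion purity is at least ``threshold`` (inclusive)."""
    return [rec for rec in records if rec.parent_purity >= threshold]


def tmt_relative_abundance(
    treated: Sequence[float], control: Sequence[float]
) -> TmtComparison:
    """Mean treated/control reporter ratio with an equal-variance t-test.

    Groups with zero pooled variance are degenerate: identical means give
    p = 1, different means a flagged p = 0.
    """
    treated = [float(v) for v in treated]
    control = [float(v) for v in control]
    if not treated or not control:
        raise ValueError("both groups must be non-empty")
    ratio = float(np.mean(treated) / np.mean(control))
    if min(len(treated), len(control)) < 2:
        return TmtComparison(ratio=ratio, p_value=None)
    if np.var(treated) == 0 and np.var(control) == 0:
        same = np.mean(treated) == np.mean(control)
        return TmtComparison(ratio=ratio, p_value=1.0 if same else 0.0, degenerate=True)
    p = float(stats.ttest_ind(treated, control, equal_var=True).pvalue)
    return TmtComparison(ratio=ratio, p_value=p)


def mito_pool_fold_change(pools: AcetylCoAPools) -> float:
    """cit1-delta vs wild-type fold change of the mitochondrial acetyl-CoA pool.

    Assumes the acetyl-CoA missing in pda1-delta cells *is* the
    mitochondrial pool, so each strain's mitochondrial pool is its total
    minus the pda1-delta total.
    """
    pools.validate()
    mito_wt = pools.total_wt - pools.total_pda1
    mito_cit1 = pools.total_cit1 - pools.total_pda1
    if mito_wt <= 0 or mito_cit1 <= 0:
        raise ValueError("pool differences vs pda1-delta must be positive")
    return mito_cit1 / mito_wt


def compartment_concentration_fold(pool_fraction: float, volume_fraction: float) -> float:
    """Concentration in a compartment relative to the rest of the cell.

    A compartment holding ``pool_fraction`` of a metabolite in
    ``volume_fraction`` of the cell volume is enriched
    ``(p/v) / ((1-p)/(1-v))``-fold over the remainder.
    """
    if not (0.0 < pool_fraction < 1.0 and 0.0 < volume_fraction < 1.0):
        raise ValueError("fractions must lie in (0, 1)")
    inside = pool_fraction / volume_fraction
    outside = (1.0 - pool_fraction) / (1.0 - volume_fraction)
    return inside / outside


def compartment_summaries(
    site_ratios: Iterable[tuple],
    proteins: Iterable[ProteinQuant] | Mapping[str, frozenset],
    reference: str = "cytoplasm",
) -> list:
    """Per-compartment median ratios with rank-sum tests vs a reference.

    ``site_ratios`` yields ``(protein_id, linear_ratio)`` pairs (already
    corrected for protein abundance where applicable); ``proteins`` is
    either ProteinQuant records or a protein -> localization-set map.
    Compartments without sites are omitted.
    """
    if isinstance(proteins, Mapping):
        loc_of = {
            pid: exclusive_localization(ProteinQuant(pid, 0.0, localizations=locs))
            for pid, locs in proteins.items()
        }
    else:
        loc_of = {p.protein_id: exclusive_localization(p) for p in proteins}
    grouped: dict[str, list[float]] = {c: [] for c in TRACKED_COMPARTMENTS}
    for protein_id, ratio in site_ratios:
        comp = loc_of.get(protein_id)
        if comp is not None and ratio > 0:
            grouped[comp].append(float(ratio))
    summaries: list[CompartmentSummary] = []
    for comp in TRACKED_COMPARTMENTS:
        ratios = grouped[comp]
        if not ratios:
            continue
        med = float(np.median(ratios))
        p = None
        if comp != reference and grouped.get(reference):
            p = wilcoxon_rank_sum(ratios, grouped[reference])
        summaries.append(
            CompartmentSummary(
                compartment=comp,
                n_sites=len(ratios),
                median_log2_ratio=math.log2(med),
                median_linear_ratio=med,
                p_vs_reference=p,
            )
        )
    return summaries
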