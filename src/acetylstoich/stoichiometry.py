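"""Acetylation-stoichiometry estimators.

Partial chemical acetylation of lysines with acetyl-phosphate (AcP)
increases a site's acetyl occupancy by a small, roughly constant amount
``c`` (the degree of chemical acetylation).  A site that started at a low
occupancy ``s0`` therefore gains acetylation in a large *relative* ratio
``R = L/H`` between the treated (light) and untreated (heavy) SILAC
channels, while a high-occupancy site barely moves.  Under the
conservative assumption that ``c < c_max`` (1% by default), the initial
occupancy is bounded by ``s0 < c_max / R``: a 10-fold increase implies
occupancy below 0.1%, a 20-fold increase below 0.05%.

Sites whose heavy (untreated) channel fell below the detection limit get
a conservative *minimum* ratio instead: the treated light intensity
divided by an empirical detection limit, the median intensity of the
bottom 10% of observed heavy peptides.

Absolute occupancies for selected peptides come from AQUA: light-channel
intensities of the acetylated and the unmodified peptide are each scaled
by a heavy spiked standard of known amount, and the occupancy is the
acetylated share of the summed amounts.

The abundance-corrected acetyl-peptide intensity I/iBAQ-A — acetyl
peptide intensity over the protein's iBAQ (total intensity per
theoretically observable tryptic peptide) — is an orthogonal,
treatment-free proxy for occupancy.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from pyteomics import parser as _pyt_parser

from .io import AquaRecord, ProteinQuant, SiteQuant, StoichEstimate

INSENSITIVE_THRESHOLD = 2.0  # L/H below this: AcP-insensitive, occupancy > c_max
HIGH_STOICH_FLAG = ">1%"
LOW_LIGHT_FLAG = "light_below_detection_limit"

# trypsin: cleave after K or R except before proline
TRYPSIN_RULE = r"[KR](?!P)"


@dataclass(frozen=True)
class DetectionLimit:
    """Empirical intensity floor for the heavy (untreated) channel."""

    value: float
    n_peptides_used: int
    bottom_fraction: float = 0.10


@dataclass
class AquaStoichiometry:
    """Absolute occupancy for one peptide, before and after AcP treatment.

    All stoichiometries are percent.  ``s_acp`` is occupancy after
    treatment, ``ratio`` the SILAC L/H fold change, ``s0 = s_acp/ratio``
    the initial occupancy and ``c = s_acp - s0`` the degree of chemical
    acetylation.  Values are stored at full precision; use
    :meth:`rounded` for report precision (s0: 4 decimals, c: 2).
    """

    peptide: str
    s_acp: float
    ratio: float
    s0: float
    c: float

    def rounded(self) -> "AquaStoichiometry":
        return AquaStoichiometry(
            peptide=self.peptide,
            s_acp=self.s_acp,
            ratio=self.ratio,
            s0=round(self.s0, 4),
            c=round(self.c, 2),
        )


# ---------------------------------------------------------------------------
# elementary estimators
# ---------------------------------------------------------------------------


def stoichiometry_upper_bound(ratio: float, c_max: float = 1.0) -> float:
    """Upper bound (percent) on initial occupancy from the SILAC fold change.

    ``c_max`` is the assumed maximum degree of chemical acetylation in
    percent.  The bound is ``c_max / ratio``; it is deliberately the
    "less-than" form rather than the exact algebra ``c_max / (ratio-1)``.
    """
    if ratio < 1:
        raise ValueError(f"upper bound undefined for ratio < 1 (got {ratio})")
    if not (c_max > 0):
        raise ValueError(f"c_max must be > 0, got {c_max}")
    return c_max / ratio


def aqua_stoichiometry(rec: AquaRecord) -> float:
    """Absolute occupancy (percent) of a site from AQUA intensities."""
    rec.validate()
    amount_ac = rec.ac_light_intensity / rec.ac_standard_intensity * rec.ac_spike_amount
    amount_unmod = (
        rec.unmod_light_intensity / rec.unmod_standard_intensity * rec.unmod_spike_amount
    )
    return 100.0 * amount_ac / (amount_ac + amount_unmod)


def initial_stoichiometry(s_acp: float, ratio: float) -> float:
    """Initial (pre-treatment) occupancy: AcP-treated occupancy over the ratio."""
    if not (s_acp > 0):
        raise ValueError(f"s_acp must be > 0, got {s_acp}")
    if ratio < 1:
        raise ValueError(f"ratio must be >= 1, got {ratio}")
    return s_acp / ratio


def chemical_acetylation_degree(s_acp: float, s0: float) -> float:
    """Occupancy added by the chemical treatment: ``s_acp - s0`` (percent)."""
    if s0 < 0 or s0 > s_acp:
        raise ValueError(f"need 0 <= s0 <= s_acp, got s0={s0}, s_acp={s_acp}")
    return s_acp - s0


def aqua_analysis(records: Iterable[AquaRecord], ratios: Mapping[str, float]) -> list:
    """Full AQUA workup: occupancy after treatment, initial occupancy and
    chemical-acetylation degree per peptide.  Peptides without a SILAC
    ratio are skipped."""
    out: list[AquaStoichiometry] = []
    for rec in records:
        ratio = ratios.get(rec.peptide)
        if ratio is None:
            continue
        s_acp = aqua_stoichiometry(rec)
        s0 = initial_stoichiometry(s_acp, ratio)
        out.append(
            AquaStoichiometry(
                peptide=rec.peptide,
                s_acp=s_acp,
                ratio=ratio,
                s0=s0,
                c=chemical_acetylation_degree(s_acp, s0),
            )
        )
    return out


def detection_limit(
    heavy_intensities: Sequence[float], bottom_fraction: float = 0.10
) -> DetectionLimit:
    """Median intensity of the bottom fraction of observed heavy peptides.

    The bottom set has ``max(1, floor(bottom_fraction * n))`` members.
    Requires at least 10 strictly positive intensities.
    """
    values = sorted(float(v) for v in heavy_intensities)
    if len(values) < 10:
        raise ValueError(f"need >= 10 intensities to set a detection limit, got {len(values)}")
    if values[0] <= 0:
        raise ValueError("all intensities must be > 0")
    k = max(1, int(bottom_fraction * len(values)))
    return DetectionLimit(
        value=statistics.median(values[:k]),
        n_peptides_used=k,
        bottom_fraction=bottom_fraction,
    )


def minimum_fold_increase(light_intensity: float, limit: DetectionLimit) -> float:
    """Conservative lower bound on R for a site without heavy signal."""
    if not (light_intensity > 0):
        raise ValueError(f"light_intensity must be > 0, got {light_intensity}")
    if not (limit.value > 0):
        raise ValueError(f"detection limit must be > 0, got {limit.value}")
    return light_intensity / limit.value


def count_observable_peptides(sequence: str, min_len: int = 7, max_len: int = 30) -> int:
    """Number of fully tryptic peptides of observable length.

    Trypsin cleaves after K or R, not before P; zero missed cleavages.
    """
    if not sequence:
        raise ValueError("empty protein sequence")
    peptides = _pyt_parser.cleave(sequence, TRYPSIN_RULE, missed_cleavages=0)
    return sum(1 for pep in peptides if min_len <= len(pep) <= max_len)


def ibaq(total_intensity: float, n_observable: int) -> float:
    """Protein intensity per theoretically observable peptide."""
    if n_observable < 1:
        raise ValueError(f"n_observable must be >= 1, got {n_observable}")
    return total_intensity / n_observable


def i_over_ibaq_a(ac_peptide_intensity: float, protein_ibaq: float) -> float:
    """Abundance-corrected acetyl-peptide intensity (untreated channel)."""
    if not (protein_ibaq > 0):
        raise ValueError(f"protein iBAQ must be > 0, got {protein_ibaq}")
    return ac_peptide_intensity / protein_ibaq


def classify_sensitivity(ratio: float | None) -> str:
    """AcP-sensitivity class: ``no_ratio`` / ``insensitive`` (R < 2) / ``sensitive``."""
    if ratio is None:
        return "no_ratio"
    return "insensitive" if ratio < INSENSITIVE_THRESHOLD else "sensitive"


# ---------------------------------------------------------------------------
# batch estimation
# ---------------------------------------------------------------------------


def _protein_ibaq(protein: ProteinQuant) -> float | None:
    if protein.ibaq is not None:
        return protein.ibaq
    if protein.sequence:
        n = count_observable_peptides(protein.sequence)
        if n >= 1:
            return ibaq(protein.total_intensity, n)
    return None


def estimate_all(
    sites: Iterable[SiteQuant],
    proteins: Iterable[ProteinQuant],
    limit: DetectionLimit,
    c_max: float = 1.0,
    natural_only: bool = True,
) -> list:
    """Estimate occupancy bounds for every site.

    Sites with a SILAC ratio >= 2 get the numeric bound ``c_max/R``;
    AcP-insensitive sites (R < 2) are flagged ``>1%`` with no numeric
    bound; sites without a ratio get a minimum ratio from the detection
    limit and the bound ``c_max/min_ratio``.  Where the protein's iBAQ is
    available the I/iBAQ-A score is attached, computed from the untreated
    (heavy) channel.
    """
    ibaq_by_protein = {p.protein_id: _protein_ibaq(p) for p in proteins}
    estimates: list[StoichEstimate] = []
    for site in sites:
        if natural_only and not site.naturally_occurring:
            continue
        est = StoichEstimate(
            protein_id=site.protein_id, position=site.position, peptide=site.peptide
        )
        if site.silac_ratio is not None:
            est.ratio = site.silac_ratio
            est.sensitivity_class = classify_sensitivity(site.silac_ratio)
            if est.sensitivity_class == "sensitive":
                est.bound_percent = stoichiometry_upper_bound(site.silac_ratio, c_max)
            else:
                est.flag = HIGH_STOICH_FLAG
        elif site.light_intensity > 0:
            est.min_ratio = minimum_fold_increase(site.light_intensity, limit)
            est.sensitivity_class = "no_ratio"
            est.bound_percent = c_max / est.min_ratio
            if est.min_ratio < 1:
                est.flag = LOW_LIGHT_FLAG
        prot_ibaq = ibaq_by_protein.get(site.protein_id)
        if prot_ibaq is not None and prot_ibaq > 0 and site.heavy_intensity is not None:
            est.i_over_ibaq_a = i_over_ibaq_a(site.heavy_intensity, prot_ibaq)
        estimates.append(est)
    return estimates


def stoichiometry_fractions(
    estimates: Iterable[StoichEstimate], thresholds: Sequence[float]
) -> dict:
    """Fraction of sites with occupancy bound below each threshold (percent).

    Sites flagged ``>1%`` count toward denominators but never toward a
    numerator (their occupancy exceeds every tabulated threshold of
    interest, which is at most 1%).
    """
    ests = [e for e in estimates if e.bound_percent is not None or e.flag == HIGH_STOICH_FLAG]
    n = len(ests)
    out: dict[float, float] = {}
    for t in thresholds:
        if n == 0:
            out[t] = 0.0
            continue
        k = sum(
            1
            for e in ests
            if e.bound_percent is not None and e.flag != HIGH_STOICH_FLAG and e.bound_percent < t
        )
        out[t] = k / n
    return out
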