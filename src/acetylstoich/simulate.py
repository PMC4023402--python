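"""Seeded generator of synthetic SILAC acetylation datasets with ground truth.

The generator emulates the statistical structure of a partial-chemical-
acetylation SILAC experiment on exponentially growing yeast:

* protein abundance is log-normal over several orders of magnitude;
* per-site initial occupancy ``s0`` (percent) is drawn from a mixture
  dominated by very low values (log-uniform over 1e-4 to 1e-1 percent),
  with a high-occupancy subpopulation (1 to 100 percent) restricted to
  nuclear proteins, and a compartment basal multiplier making
  mitochondrial occupancy a few-fold higher than cytoplasmic;
* treatment converts a fraction of the *unmodified* lysines, so the
  treated occupancy is ``s1 = s0 + c * (1 - s0/100)`` where the per-lysine
  reactivity ``c`` is log-normal with median 0.07 percent (measured range
  roughly 0.01-0.11 percent), truncated at 1 percent;
* channel intensities are proportional to protein abundance times
  occupancy with multiplicative log-normal noise, and heavy (untreated)
  intensities below a detection threshold are censored.

All sampling flows from a single integer seed; identical configurations
produce byte-identical output tables.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io import AquaRecord, ProteinQuant, SiteQuant, TmtRecord

_AMINO_ACIDS = np.array(list("ADEFGHILMNQSTVWY"))  # no K/R/C/P: inert peptide body


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic experiment.

    Units: stoichiometries and reactivities in percent, intensities in
    arbitrary MS intensity units, ``abundance_log_mean``/``_sd`` on the
    natural-log scale.
    """

    n_proteins: int = 400
    abundance_log_mean: float = 18.0  # median protein abundance ~6.6e7
    abundance_log_sd: float = 2.3  # ~1 decade sd: yeast abundances span ~4 decades
    compartment_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "mitochondrion": 0.20,
            "cytoplasm": 0.40,
            "nucleus": 0.25,
            "other": 0.15,
        }
    )
    dual_localization_fraction: float = 0.10
    sites_per_protein: float = 3.0  # Poisson mean
    low_stoich_range: tuple = (1e-4, 1e-1)  # percent, log-uniform
    high_stoich_fraction_nuclear: float = 0.25
    high_stoich_range: tuple = (1.0, 100.0)  # percent, log-uniform
    reactivity_median: float = 0.07  # percent
    reactivity_log_sd: float = 0.6
    reactivity_max: float = 1.0  # percent; truncation
    compartment_basal_multiplier: Mapping[str, float] = field(
        default_factory=lambda: {
            "mitochondrion": 3.0,
            "cytoplasm": 1.0,
            "nucleus": 1.0,
            "other": 1.0,
        }
    )
    noise_cv: float = 0.15
    detection_threshold: float = 2000.0
    natural_fraction: float = 0.6
    mean_observable_peptides: float = 20.0
    protein_ratio_log_sd: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.n_proteins < 1:
            problems.append("n_proteins must be >= 1")
        if abs(sum(self.compartment_probs.values()) - 1.0) > 1e-9:
            problems.append("compartment_probs must sum to 1")
        for name in ("low_stoich_range", "high_stoich_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                problems.append(f"{name} must be a positive increasing interval")
        if not (self.detection_threshold > 0):
            problems.append("detection_threshold must be > 0")
        if not (0 < self.reactivity_median <= self.reactivity_max):
            problems.append("reactivity_median must lie in (0, reactivity_max]")
        for name in (
            "high_stoich_fraction_nuclear",
            "natural_fraction",
            "dual_localization_fraction",
        ):
            if not (0.0 <= getattr(self, name) <= 1.0):
                problems.append(f"{name} must lie in [0, 1]")
        if self.noise_cv < 0:
            problems.append("noise_cv must be >= 0")
        if problems:
            raise ValueError("invalid GeneratorConfig: " + "; ".join(problems))


@dataclass
class TruthRecord:
    """Ground truth for one synthetic site."""

    protein_id: str
    position: int
    true_stoichiometry: float  # percent, before treatment
    reactivity: float  # percent added to the unmodified fraction
    compartment: str
    censored_heavy: bool

    @property
    def treated_stoichiometry(self) -> float:
        return self.true_stoichiometry + self.reactivity * (1.0 - self.true_stoichiometry / 100.0)

    @property
    def true_ratio(self) -> float:
        return self.treated_stoichiometry / self.true_stoichiometry


@dataclass
class SimulatedDataset:
    sites: list
    proteins: list
    heavy_intensities: list  # observed (uncensored) heavy-channel intensities
    truth: list
    config: GeneratorConfig


def _lognormal_noise(rng: np.random.Generator, cv: float, size=None):
    if cv <= 0:
        return np.ones(size) if size is not None else 1.0
    sigma = np.sqrt(np.log(1.0 + cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def _sample_reactivity(rng: np.random.Generator, cfg: GeneratorConfig) -> float:
    # truncation by resampling keeps the log-normal shape below the cap
    mu = np.log(cfg.reactivity_median)
    for _ in range(1000):
        c = float(rng.lognormal(mean=mu, sigma=cfg.reactivity_log_sd))
        if c <= cfg.reactivity_max:
            return c
    return cfg.reactivity_max


def _peptide(rng: np.random.Generator) -> str:
    body = "".join(rng.choice(_AMINO_ACIDS, size=7))
    tail = "".join(rng.choice(_AMINO_ACIDS, size=2))
    return f"{body}K(ac){tail}K"


def generate_dataset(config: GeneratorConfig | None = None) -> SimulatedDataset:
    """Simulate one AcP-treated (light) vs untreated (heavy) experiment."""
    cfg = config or GeneratorConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    compartments = list(cfg.compartment_probs)
    probs = np.array([cfg.compartment_probs[c] for c in compartments])

    sites: list[SiteQuant] = []
    proteins: list[ProteinQuant] = []
    heavy_observed: list[float] = []
    truth: list[TruthRecord] = []

    for p_index in range(cfg.n_proteins):
        pid = f"SYN{p_index:04d}"
        abundance = float(rng.lognormal(cfg.abundance_log_mean, cfg.abundance_log_sd))
        compartment = compartments[int(rng.choice(len(compartments), p=probs))]
        locs = {compartment}
        if rng.random() < cfg.dual_localization_fraction:
            extra = compartments[int(rng.choice(len(compartments), p=probs))]
            locs.add(extra)
        n_obs = 1 + int(rng.poisson(cfg.mean_observable_peptides - 1))
        proteins.append(
            ProteinQuant(
                protein_id=pid,
                total_intensity=abundance * n_obs * float(_lognormal_noise(rng, cfg.noise_cv)),
                silac_ratio=float(rng.lognormal(0.0, cfg.protein_ratio_log_sd)),
                localizations=frozenset(locs),
                n_observable_peptides=n_obs,
            )
        )
        n_sites = int(rng.poisson(cfg.sites_per_protein))
        if n_sites == 0:
            continue
        positions = rng.choice(np.arange(1, 1001), size=n_sites, replace=False)
        for position in sorted(int(x) for x in positions):
            nuclear_high = (
                compartment == "nucleus" and rng.random() < cfg.high_stoich_fraction_nuclear
            )
            lo, hi = cfg.high_stoich_range if nuclear_high else cfg.low_stoich_range
            s0 = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            if not nuclear_high:
                s0 *= cfg.compartment_basal_multiplier.get(compartment, 1.0)
            s0 = min(s0, 99.0)
            c = _sample_reactivity(rng, cfg)
            s1 = s0 + c * (1.0 - s0 / 100.0)
            heavy = abundance * (s0 / 100.0) * float(_lognormal_noise(rng, cfg.noise_cv))
            light = abundance * (s1 / 100.0) * float(_lognormal_noise(rng, cfg.noise_cv))
            censored = heavy < cfg.detection_threshold
            natural = bool(rng.random() < cfg.natural_fraction)
            peptide = _peptide(rng)
            if censored:
                sites.append(
                    SiteQuant(pid, position, peptide, light, None, None, natural)
                )
            else:
                heavy_observed.append(heavy)
                sites.append(
                    SiteQuant(pid, position, peptide, light, heavy, light / heavy, natural)
                )
            truth.append(
                TruthRecord(
                    protein_id=pid,
                    position=position,
                    true_stoichiometry=s0,
                    reactivity=c,
                    compartment=compartment,
                    censored_heavy=censored,
                )
            )
    return SimulatedDataset(sites, proteins, heavy_observed, truth, cfg)


def generate_aqua_fixture(
    truth: Sequence[TruthRecord],
    spike_amounts: tuple = (1.0, 100.0),
    noise_cv: float = 0.0,
    total_amount: float = 100.0,
    seed: int = 0,
) -> list:
    """AQUA intensity records consistent with the true treated occupancies.

    ``spike_amounts`` are the (acetylated, unmodified) standard amounts.
    With zero noise, :func:`~acetylstoich.stoichiometry.aqua_stoichiometry`
    recovers each site's treated occupancy exactly.
    """
    rng = np.random.default_rng(seed)
    ac_spike, unmod_spike = spike_amounts
    records: list[AquaRecord] = []
    for i, rec in enumerate(truth):
        s1 = rec.treated_stoichiometry
        amount_ac = s1 / 100.0 * total_amount
        amount_unmod = total_amount - amount_ac
        # per-peptide-form MS response factor; cancels only without noise
        k_ac = float(rng.lognormal(0.0, 0.3))
        k_unmod = float(rng.lognormal(0.0, 0.3))
        records.append(
            AquaRecord(
                peptide=f"{rec.protein_id}_K{rec.position}",
                ac_light_intensity=amount_ac * k_ac * float(_lognormal_noise(rng, noise_cv)),
                ac_standard_intensity=ac_spike * k_ac * float(_lognormal_noise(rng, noise_cv)),
                unmod_light_intensity=amount_unmod
                * k_unmod
                * float(_lognormal_noise(rng, noise_cv)),
                unmod_standard_intensity=unmod_spike
                * k_unmod
                * float(_lognormal_noise(rng, noise_cv)),
                ac_spike_amount=ac_spike,
                unmod_spike_amount=unmod_spike,
            )
        )
    return records


def generate_tmt_fixture(
    n_peptides: int,
    dose_effects: Mapping[float, float],
    purity_values: Sequence[float] | None = None,
    acetylated_fraction: float = 0.5,
    noise_cv: float = 0.10,
    seed: int = 0,
) -> tuple:
    """TMT reporter records for a dose-response acetylation experiment.

    Channel 0 is the untreated control; the remaining channels follow the
    ``dose_effects`` mapping (dose -> fold change of *acetylated* peptide
    abundance).  Non-acetylated peptide channels stay flat.  Returns
    ``(records, doses)`` with ``doses`` aligned to channels 1..n.

    ``purity_values``, when given, are cycled over the records; otherwise
    purities are sampled with most spectra clean (>= 0.9) and a minority
    co-isolated, so the 90% purity filter is exercised.
    """
    rng = np.random.default_rng(seed)
    doses = sorted(dose_effects)
    records: list[TmtRecord] = []
    for i in range(n_peptides):
        is_ac = rng.random() < acetylated_fraction
        base = float(rng.lognormal(10.0, 0.5))
        channels = [base * float(_lognormal_noise(rng, noise_cv))]
        for dose in doses:
            effect = dose_effects[dose] if is_ac else 1.0
            channels.append(base * effect * float(_lognormal_noise(rng, noise_cv)))
        if purity_values is not None:
            purity = float(purity_values[i % len(purity_values)])
        elif rng.random() < 0.8:
            purity = float(rng.uniform(0.90, 1.0))
        else:
            purity = float(rng.uniform(0.5, 0.90))
        records.append(
            TmtRecord(
                peptide=f"TMTPEP{i:04d}",
                is_acetylated=bool(is_ac),
                reporter_intensities=tuple(channels),
                parent_purity=purity,
            )
        )
    return records, doses


TRUTH_COLUMNS = (
    "protein_id",
    "position",
    "true_stoichiometry",
    "reactivity",
    "compartment",
    "censored_heavy",
)


def write_truth_table(path, truth: Sequence[TruthRecord]) -> None:
    """Write ground truth as TSV (floats at full repr precision)."""
    import csv
    from pathlib import Path

    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(TRUTH_COLUMNS)
        for rec in truth:
            writer.writerow(
                [
                    rec.protein_id,
                    rec.position,
                    repr(rec.true_stoichiometry),
                    repr(rec.reactivity),
                    rec.compartment,
                    "true" if rec.censored_heavy else "false",
                ]
            )


def read_truth_table(path) -> list:
    """Read a ground-truth table written by :func:`write_truth_table`."""
    from .io import _open_rows, _req_float

    records: list[TruthRecord] = []
    for i, row in _open_rows(path, TRUTH_COLUMNS, None):
        records.append(
            TruthRecord(
                protein_id=row["protein_id"],
                position=int(row["position"]),
                true_stoichiometry=_req_float(row["true_stoichiometry"], "true_stoichiometry"),
                reactivity=_req_float(row["reactivity"], "reactivity"),
                compartment=row["compartment"],
                censored_heavy=row["censored_heavy"].lower() in ("true", "1", "yes"),
            )
        )
    return records


def tmt_dose_groups(records: Sequence[TmtRecord], doses: Sequence[float], dose: float) -> tuple:
    """Extract (treated, control) reporter vectors for one dose across
    acetylated peptides; peptides are the replicates."""
    channel = 1 + list(doses).index(dose)
    treated = [r.reporter_intensities[channel] for r in records if r.is_acetylated]
    control = [r.reporter_intensities[0] for r in records if r.is_acetylated]
    return treated, control
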