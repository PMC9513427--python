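"""Seeded synthetic qPCR data with known ground truth.

The generator emulates the three input table kinds — dilution series, Cq
experiments and RNA concentration measurements — under a simple first-order
noise model: Gaussian perturbations on the Cq scale, independent between the
biological and technical levels.  At zero noise every pipeline recovers the
configured truth exactly, which anchors the test suite; with noise the
generators drive parameter-recovery and calibration studies.

Ground-truth model for a gene g with amplification factor A_g and baseline
``base_cq`` (the Cq of the control condition):

    Cq(dilution step k)      = base_cq + k * log_{A_g}(dilution_factor)
    Cq(group with fold F)    = base_cq - log_{A_g}(F) + bio noise + tech noise
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class GeneSpec:
    """True per-gene parameters: per-cycle amplification factor and baseline Cq."""

    amp_factor: float = 2.0
    base_cq: float = 24.0

    def __post_init__(self):
        if self.amp_factor <= 1:
            raise ValueError("amp_factor must be > 1")


@dataclass(frozen=True)
class SimulationConfig:
    """Study design for the synthetic generators.

    ``fold_changes`` maps group -> gene -> true relative expression versus
    the control group (the first group listed); reference-style genes simply
    carry fold 1.0 in every group.  ``cq_noise_sd`` is the technical
    (well-level) Gaussian SD in cycles; ``bio_noise_sd`` is an extra
    replicate-level SD shared by a biological replicate's wells.
    """

    seed: int = 0
    genes: dict = field(default_factory=lambda: {"target": GeneSpec(), "ref": GeneSpec()})
    fold_changes: dict = field(default_factory=lambda: {
        "control": {"target": 1.0, "ref": 1.0},
        "treatment": {"target": 4.0, "ref": 1.0},
    })
    n_bio: int = 3
    n_tech: int = 3
    cq_noise_sd: float = 0.0
    bio_noise_sd: float = 0.0
    dilution_steps: int = 5
    dilution_factor: float = 10.0

    def __post_init__(self):
        if self.n_bio < 1 or self.n_tech < 1:
            raise ValueError("n_bio and n_tech must be >= 1")
        if self.cq_noise_sd < 0 or self.bio_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        for group, per_gene in self.fold_changes.items():
            if any(f <= 0 for f in per_gene.values()):
                raise ValueError(f"fold changes must be positive (group {group!r})")

    @property
    def control_group(self) -> str:
        return next(iter(self.fold_changes))


def simulate_dilution_series(config: SimulationConfig) -> pd.DataFrame:
    """Serial-dilution Cq table for every configured gene.

    Cq rises by ``log_A(dilution_factor)`` per dilution step plus optional
    Gaussian noise; at zero noise the standard-curve fit returns each gene's
    amplification factor exactly.
    """
    if config.dilution_steps < 3:
        raise ValueError("at least 3 dilution steps are required for a curve")
    rng = np.random.default_rng(config.seed)
    rows = []
    for gene, spec in config.genes.items():
        step_cycles = np.log(config.dilution_factor) / np.log(spec.amp_factor)
        for step in range(config.dilution_steps):
            for _ in range(config.n_tech):
                cq = spec.base_cq + step * step_cycles + rng.normal(0, config.cq_noise_sd)
                rows.append({"gene": gene,
                             "rel_conc": config.dilution_factor ** (-step),
                             "cq": cq})
    out = pd.DataFrame(rows)
    out.attrs["dilution_factor"] = config.dilution_factor
    return out


def simulate_cq_experiment(config: SimulationConfig) -> pd.DataFrame:
    """Long-format Cq table over groups x biological x technical replicates.

    A group's true fold change F shifts that gene's Cq by ``-log_A(F)``;
    biological noise is shared within a replicate, technical noise is
    per well.  Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(config.seed + 1)
    rows = []
    for gene, spec in config.genes.items():
        log_a = np.log(spec.amp_factor)
        for group, per_gene in config.fold_changes.items():
            fold = per_gene.get(gene, 1.0)
            true_cq = spec.base_cq - np.log(fold) / log_a
            for bio in range(1, config.n_bio + 1):
                bio_shift = rng.normal(0, config.bio_noise_sd)
                for tech in range(1, config.n_tech + 1):
                    rows.append({
                        "gene": gene, "group": group, "bio_rep": bio, "tech_rep": tech,
                        "cq": true_cq + bio_shift + rng.normal(0, config.cq_noise_sd),
                    })
    return pd.DataFrame(rows)


def simulate_concentrations(means: dict, n_reps: int = 3, cv: float = 0.0,
                            seed: int = 0) -> pd.DataFrame:
    """RNA concentration table with replicate measurements around given means.

    Parameters
    ----------
    means : dict
        Maps sample name to its true mean concentration (ng/ul).
    cv : float
        Coefficient of variation of the replicate measurements; 0 gives
        replicates exactly equal to the mean.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for sample, mean in means.items():
        if mean <= 0:
            raise ValueError(f"sample {sample!r}: mean concentration must be positive")
        for _ in range(n_reps):
            conc = mean * (1 + rng.normal(0, cv)) if cv > 0 else mean
            rows.append({"sample": sample, "conc": max(conc, 1e-9)})
    return pd.DataFrame(rows)


def true_fold_change(config: SimulationConfig, gene: str, group: str) -> float:
    """Ground-truth fold change of ``gene`` in ``group`` versus the control group."""
    fc = config.fold_changes[group].get(gene, 1.0)
    ctrl = config.fold_changes[config.control_group].get(gene, 1.0)
    return fc / ctrl
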