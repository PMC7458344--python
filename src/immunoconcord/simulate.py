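"""Synthetic pancreatic-tumor cohorts with the structure the analysis assumes.

Each cohort couples, per patient, a latent immune-infiltration state to
every data modality the pipeline consumes:

* latent CD3/CD8/CD68 cell densities, log-normal with configurable
  correlations (CD8 tracks CD3 tightly; CD68 only weakly);
* observed IHC densities = latent density x multiplicative log-normal
  measurement noise;
* an emulated deconvolution score matrix over the 22-type catalog, whose
  marker-composite constituents partition the latent density through a
  fixed Dirichlet draw and are zeroed with probability logistic in
  log(latent / dropout_scale) — the detection-floor dropout seen in real
  deconvolution of poorly infiltrated tumors;
* a TPM expression matrix with planted infiltration-responsive genes whose
  log-expression shifts by ``effect_size`` per standardized latent CD3 unit;
* exponential survival times whose hazard falls with T-cell infiltration,
  right-censored by an independent exponential clock.

Defaults are order-of-magnitude choices for a resected pancreatic
adenocarcinoma cohort, not estimates of any particular study population.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit

from .composites import LM22_CATALOG, default_mapping
from .io import (
    DeconvolutionResult,
    ExpressionMatrix,
    IHCRecord,
    write_deconvolution,
    write_expression,
    write_ihc,
)

# latent mean offsets on the log scale relative to CD3: CD8 T cells are a
# subset of CD3 T cells (~2.5x fewer); macrophages are of the same order.
CD8_LOG_OFFSET = -np.log(2.5)
CD68_LOG_OFFSET = 0.0
#: steepness of the logistic detection-floor dropout curve
DROPOUT_STEEPNESS = 1.5
#: deconvolution score units per cell/mm^2 (arbitrary-semantics scale)
SCORE_PER_DENSITY = 1e-4
#: spread of per-gene baseline log2 expression means around baseline_log_mean
GENE_MEAN_SD = 1.5


@dataclass
class SimulationConfig:
    """Parameters of a simulated cohort.

    Densities are cells/mm^2, times in months.  ``effect_size`` is the
    additive log2-expression shift of a planted gene per standard deviation
    of latent log CD3 density; ``baseline_log_sd`` is the per-sample
    residual noise on the log2 scale against which it is measured.
    """

    n_patients: int = 39
    seed: int = 0
    cd3_log_mean: float = np.log(300.0)
    cd3_log_sd: float = 1.0
    rho_cd3_cd8: float = 0.8
    rho_cd3_cd68: float = 0.2
    ihc_noise_sd: float = 0.1
    dropout_scale: float = 30.0
    n_genes: int = 1000
    n_signature_genes: int = 30
    effect_size: float = 1.0
    baseline_log_mean: float = 3.0
    baseline_log_sd: float = 1.0
    hazard_base: float = 0.02
    hazard_log_ratio: float = -0.5
    censor_rate: float = 0.01

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        for name in ("cd3_log_sd", "dropout_scale", "baseline_log_sd", "hazard_base", "censor_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.ihc_noise_sd < 0:
            raise ValueError("ihc_noise_sd must be non-negative")
        if not 0 <= self.rho_cd3_cd8 <= 1:
            raise ValueError("rho_cd3_cd8 must be in [0, 1]")
        if not -1 <= self.rho_cd3_cd68 <= 1:
            raise ValueError("rho_cd3_cd68 must be in [-1, 1]")
        if not 0 <= self.n_signature_genes <= self.n_genes:
            raise ValueError("n_signature_genes must be within [0, n_genes]")

    def correlation_matrix(self) -> np.ndarray:
        """Latent (CD3, CD8, CD68) log-scale correlation matrix.

        CD8 and CD68 are conditionally independent given CD3 (chain
        structure), so their cross-correlation is the product of the two
        configured correlations; the result is positive semi-definite for
        all in-range inputs, but definiteness is still verified.
        """
        a, b = self.rho_cd3_cd8, self.rho_cd3_cd68
        R = np.array([[1.0, a, b], [a, 1.0, a * b], [b, a * b, 1.0]])
        evals = np.linalg.eigvalsh(R)
        if evals.min() < -1e-10:
            pair = "cd3/cd8" if abs(a) > abs(b) else "cd3/cd68"
            raise ValueError(f"correlation matrix not positive semi-definite (check {pair} correlation)")
        return R


@dataclass
class SyntheticCohort:
    """One simulated cohort plus the ground truth that generated it."""

    ihc: list[IHCRecord]
    expression: ExpressionMatrix
    decon: dict[str, DeconvolutionResult]
    truth: pd.DataFrame  # per-patient latent densities and standardized CD3
    planted_genes: list[str]
    config: SimulationConfig


def simulate_cohort(config: SimulationConfig, seed: Optional[int] = None) -> SyntheticCohort:
    """Draw a complete cohort under ``config`` (see module docstring).

    ``seed`` overrides ``config.seed`` when given.  Identical config and
    seed yield bit-identical cohorts.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_patients
    patients = [f"P{i + 1:04d}" for i in range(n)]

    # latent log densities
    R = config.correlation_matrix()
    means = np.array(
        [config.cd3_log_mean, config.cd3_log_mean + CD8_LOG_OFFSET, config.cd3_log_mean + CD68_LOG_OFFSET]
    )
    cov = R * config.cd3_log_sd**2
    log_latent = rng.multivariate_normal(means, cov, size=n, method="eigh")
    latent = np.exp(log_latent)  # columns: cd3, cd8, cd68
    z_cd3 = (log_latent[:, 0] - config.cd3_log_mean) / config.cd3_log_sd

    # observed IHC densities: multiplicative log-normal measurement noise
    noise = np.exp(rng.normal(0.0, config.ihc_noise_sd, size=(n, 3))) if config.ihc_noise_sd > 0 else np.ones((n, 3))
    observed = latent * noise

    # survival: exponential hazard decreasing with standardized CD3
    hazard = config.hazard_base * np.exp(config.hazard_log_ratio * z_cd3)
    event_time = rng.exponential(1.0 / hazard)
    censor_time = rng.exponential(1.0 / config.censor_rate, size=n)
    time = np.minimum(event_time, censor_time)
    event = event_time <= censor_time

    ihc = [
        IHCRecord(
            patient=patients[i],
            cd3=float(observed[i, 0]),
            cd8=float(observed[i, 1]),
            cd68=float(observed[i, 2]),
            time=float(time[i]),
            event=bool(event[i]),
            pathology="PDA",
        )
        for i in range(n)
    ]

    decon = {"cibersort-like": _simulate_deconvolution(rng, config, patients, latent)}
    expression, planted = _simulate_expression(rng, config, patients, z_cd3)

    truth = pd.DataFrame(
        {
            "latent_cd3": latent[:, 0],
            "latent_cd8": latent[:, 1],
            "latent_cd68": latent[:, 2],
            "z_cd3": z_cd3,
            "event_time": event_time,
            "censor_time": censor_time,
        },
        index=pd.Index(patients, name="patient"),
    )
    return SyntheticCohort(ihc=ihc, expression=expression, decon=decon, truth=truth, planted_genes=planted, config=config)


def _simulate_deconvolution(rng, config, patients, latent) -> DeconvolutionResult:
    """Emulated 22-type deconvolution output driven by the latent densities.

    Composite constituents partition the marker's latent density through a
    Dirichlet weight vector fixed per cohort, so the sum-rule composite
    recovers the latent signal exactly in the noise-free limit.  Because
    the CD8 subset is shared between the CD3 and CD8 composites, its share
    is the latent CD8 density (clamped below the CD3 density) and the
    remaining CD3 subsets partition the residual.  Every score is then
    zeroed with probability rising as its driving density falls below the
    dropout scale.
    """
    mapping = default_mapping("cibersort_lm22")
    n = len(patients)
    scores = pd.DataFrame(0.0, index=list(LM22_CATALOG), columns=patients)

    cd3_lat, cd8_lat, cd68_lat = latent[:, 0], latent[:, 1], latent[:, 2]
    cd8_share = np.minimum(cd8_lat, 0.95 * cd3_lat)

    cd3_members = [c for c in mapping.constituents("CD3") if c != "T cells CD8"]
    w_cd3 = rng.dirichlet(np.ones(len(cd3_members)))
    scores.loc["T cells CD8"] = cd8_share
    for j, cell in enumerate(cd3_members):
        scores.loc[cell] = w_cd3[j] * (cd3_lat - cd8_share)

    cd68_members = list(mapping.constituents("CD68"))
    w_cd68 = rng.dirichlet(np.ones(len(cd68_members)))
    for j, cell in enumerate(cd68_members):
        scores.loc[cell] = w_cd68[j] * cd68_lat

    composite_members = set(mapping.constituents("CD3")) | set(cd68_members)
    others = [c for c in LM22_CATALOG if c not in composite_members]
    other_latent = np.exp(rng.normal(config.cd3_log_mean - 2.0, 1.0, size=(len(others), n)))
    scores.loc[others] = other_latent

    # detection-floor dropout, driven by each score's underlying density
    density = scores.to_numpy()
    with np.errstate(divide="ignore"):
        logratio = np.log(np.where(density > 0, density, np.finfo(float).tiny) / config.dropout_scale)
    p_drop = expit(-DROPOUT_STEEPNESS * logratio)
    dropped = rng.random(density.shape) < p_drop
    kept = np.where(dropped, 0.0, density) * SCORE_PER_DENSITY
    return DeconvolutionResult(pd.DataFrame(kept, index=scores.index, columns=patients), method="cibersort-like", semantics="arbitrary")


def _simulate_expression(rng, config, patients, z_cd3) -> tuple[ExpressionMatrix, list[str]]:
    n = len(patients)
    genes = [f"G{i + 1:05d}" for i in range(config.n_genes)]
    planted_idx = rng.choice(config.n_genes, size=config.n_signature_genes, replace=False)
    planted = sorted(genes[i] for i in planted_idx)
    mu = rng.normal(config.baseline_log_mean, GENE_MEAN_SD, size=config.n_genes)
    log_expr = mu[:, None] + rng.normal(0.0, config.baseline_log_sd, size=(config.n_genes, n))
    log_expr[planted_idx, :] += config.effect_size * z_cd3[None, :]
    tpm = np.power(2.0, log_expr)
    expr = ExpressionMatrix(pd.DataFrame(tpm, index=genes, columns=patients), transform="tpm")
    return expr, planted


def write_cohort(cohort: SyntheticCohort, outdir) -> None:
    """Write a cohort in the pipeline's on-disk formats plus ground truth.

    Emits ``expression.tsv``, ``ihc.csv``, one ``decon_<method>.tsv`` per
    emulated method, ``truth.tsv`` and ``planted_genes.txt``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_expression(cohort.expression, outdir / "expression.tsv")
    write_ihc(cohort.ihc, outdir / "ihc.csv")
    for method, decon in cohort.decon.items():
        safe = method.replace("/", "_").replace(" ", "_")
        write_deconvolution(decon, outdir / f"decon_{safe}.tsv")
    cohort.truth.to_csv(outdir / "truth.tsv", sep="\t", lineterminator="\n")
    (outdir / "planted_genes.txt").write_text("\n".join(cohort.planted_genes) + "\n", encoding="utf-8")
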