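"""Synthetic expression and dose-response data with known ground truth.

The expression generator plants three melanoma-like subtypes on top of a
bimodal (silenced/expressed) log2 background:

* seven named receptor tyrosine kinase genes (AXL, EGFR, EPHA2, ERBB3, MERTK,
  PDGFRA, PDGFRB) follow the characteristic subtype direction pattern —
  S1 = EGFR-high/ERBB3-low invasive, S2 = EGFR-low/ERBB3-high invasive,
  S3 = EGFR-low/ERBB3-high proliferative (MITF-type, AXL/EGFR low);
* one disjoint block of marker genes per subtype, up in that subtype only;
* optional per-batch gene-wise additive shifts and multiplicative scale
  factors applied to the noise term, mirroring the location/scale model that
  empirical-Bayes batch correction assumes.

Default subtype prevalences (11/9/25) mimic the unbalanced ~25/20/55% split
observed in cell-line cohorts.  Dose-response tables are drawn from either a
median-effect model fa/(1-fa) = (D/Dm)^m or a four-parameter logistic
viability curve, with Gaussian noise truncated to [0, 1.2].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "RTK_GENES",
    "RTK_DIRECTIONS",
    "ExpressionSimConfig",
    "SimulatedDataset",
    "generate_expression",
    "DoseResponseSimConfig",
    "generate_dose_response",
    "generate_combination",
]

SUBTYPES = ("S1", "S2", "S3")

RTK_GENES = ("AXL", "EGFR", "EPHA2", "ERBB3", "MERTK", "PDGFRA", "PDGFRB")

# direction weights per subtype; +-1 = strong, +-0.5 = moderate.  Effect on the
# log2 mean is weight * marker_effect / 2, so strong-high vs strong-low genes
# differ by exactly marker_effect.
RTK_DIRECTIONS: dict[str, tuple[float, float, float]] = {
    "AXL": (1.0, 1.0, -1.0),
    "EGFR": (1.0, -0.5, -1.0),
    "EPHA2": (0.5, 0.5, -0.5),
    "ERBB3": (-1.0, 1.0, 1.0),
    "MERTK": (-1.0, -1.0, 0.5),
    "PDGFRA": (0.5, -0.5, -0.5),
    "PDGFRB": (0.5, -0.5, -0.5),
}

# sampling weights of the echo patterns (AXL, EGFR, EPHA2, ERBB3, MERTK,
# PDGFRA, PDGFRB order): the broad receptor panel is dominated by the
# EGFR/ERBB3-type mutually exclusive axis that drives the two-cluster split
RTK_ECHO_WEIGHTS = (0.5, 3.0, 0.5, 3.0, 0.5, 2.5, 2.5)

# default doses: the 7-point PLX4720/Dasatinib series (uM)
DEFAULT_DOSES = (0.004, 0.016, 0.063, 0.25, 1.0, 4.0, 16.0)


@dataclass
class ExpressionSimConfig:
    """Parameters of the planted-subtype expression generator."""

    n_samples_per_subtype: tuple[int, int, int] = (11, 9, 25)
    n_genes: int = 500
    n_rtk_like: int = 27  # extra RTK-panel genes echoing the canonical patterns
    n_marker_genes_per_block: int = 30
    n_invasive_program_genes: int = 20  # shared invasive (EMT-like) program
    marker_effect: float = 3.0
    noise_sd: float = 1.0
    silenced_mean: float = 4.0
    expressed_mean: float = 8.0
    expressed_fraction: float = 0.6
    n_batches: int = 1
    batch_shift_sd: float = 1.0
    batch_scale_sd: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if len(self.n_samples_per_subtype) != 3:
            raise ValueError("n_samples_per_subtype must have 3 entries")
        if any(n < 2 for n in self.n_samples_per_subtype):
            raise ValueError(
                "every subtype needs >= 2 samples (cross-validation and "
                "silhouette are undefined below that)"
            )
        if self.marker_effect <= 0:
            raise ValueError("marker_effect must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.expressed_mean <= self.silenced_mean:
            raise ValueError("expressed_mean must exceed silenced_mean")
        if self.n_batches < 1:
            raise ValueError("n_batches must be >= 1")
        if self.n_rtk_like < 0:
            raise ValueError("n_rtk_like must be >= 0")
        if self.n_invasive_program_genes < 0:
            raise ValueError("n_invasive_program_genes must be >= 0")
        needed = (
            len(RTK_GENES)
            + self.n_rtk_like
            + self.n_invasive_program_genes
            + 3 * self.n_marker_genes_per_block
        )
        if self.n_genes < needed:
            raise ValueError(f"n_genes must be >= {needed} for this configuration")


@dataclass
class SimulatedDataset:
    """A generated cohort together with its generative ground truth."""

    matrix: pd.DataFrame  # genes x samples, log2
    true_subtype: pd.Series
    true_batch: pd.Series
    true_marker_sets: dict[str, list[str]]
    truth_manifest: dict

    @property
    def rtk_genes(self) -> list[str]:
        """The full RTK panel: canonical genes plus the RTK-like extras."""
        return list(self.truth_manifest["rtk_panel"])

    @property
    def mpse_genes(self) -> list[str]:
        """Phenotype signature genes: the shared invasive program plus the
        proliferative (S3) marker block — genes that separate invasive from
        proliferative samples without discriminating S1 from S2."""
        return list(
            self.truth_manifest["invasive_program_genes"]
            + self.true_marker_sets["S3"]
        )

    @property
    def true_phenotype(self) -> pd.Series:
        """Invasive for S1/S2, Proliferative for S3 (the planted convention)."""
        mapping = {"S1": "Invasive", "S2": "Invasive", "S3": "Proliferative"}
        return self.true_subtype.map(mapping).rename("phenotype")


def generate_expression(config: ExpressionSimConfig) -> SimulatedDataset:
    """Generate a log2 expression matrix with planted subtype/batch structure."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    ns = config.n_samples_per_subtype
    n = int(sum(ns))
    subtype = np.repeat(SUBTYPES, ns)
    sample_ids = [f"SAMPLE_{i + 1:03d}" for i in range(n)]

    mid = 0.5 * (config.silenced_mean + config.expressed_mean)
    half = 0.5 * config.marker_effect

    n_block = config.n_marker_genes_per_block
    marker_sets = {
        s: [f"MK{k + 1}_{j + 1:03d}" for j in range(n_block)]
        for k, s in enumerate(SUBTYPES)
    }
    rtk_like = [f"RTKL_{j + 1:03d}" for j in range(config.n_rtk_like)]
    inv_program = [f"INV_{j + 1:03d}" for j in range(config.n_invasive_program_genes)]
    n_bg = (
        config.n_genes
        - len(RTK_GENES)
        - config.n_rtk_like
        - len(inv_program)
        - 3 * n_block
    )
    bg_genes = [f"BG_{j + 1:04d}" for j in range(n_bg)]
    genes = (
        list(RTK_GENES)
        + rtk_like
        + inv_program
        + [g for s in SUBTYPES for g in marker_sets[s]]
        + bg_genes
    )

    # per-gene, per-subtype means
    means = np.empty((len(genes), 3))
    row = 0
    for g in RTK_GENES:
        means[row] = mid + half * np.asarray(RTK_DIRECTIONS[g])
        row += 1
    # RTK-like panel genes echo a canonical direction pattern, attenuated,
    # emulating the wider receptor panel real cohorts are clustered on.
    # Echo weights favor the EGFR/ERBB3-type mutually exclusive axis, which
    # dominates the two-cluster split of real RTK panels.
    canon = np.array([RTK_DIRECTIONS[g] for g in RTK_GENES])
    echo_w = np.asarray(RTK_ECHO_WEIGHTS, float)
    picks = rng.choice(len(RTK_GENES), config.n_rtk_like, p=echo_w / echo_w.sum())
    atten = rng.uniform(0.5, 1.0, config.n_rtk_like)
    for j in range(config.n_rtk_like):
        means[row] = mid + half * atten[j] * canon[picks[j]]
        row += 1
    # shared invasive program: up in both invasive subtypes, down in S3
    means[row : row + len(inv_program)] = [
        config.expressed_mean,
        config.expressed_mean,
        config.expressed_mean - config.marker_effect,
    ]
    row += len(inv_program)
    for k in range(3):
        block = np.full(3, config.expressed_mean - config.marker_effect)
        block[k] = config.expressed_mean
        means[row : row + n_block] = block
        row += n_block
    bg_state = rng.random(n_bg) < config.expressed_fraction
    bg_mean = np.where(bg_state, config.expressed_mean, config.silenced_mean)
    means[row:] = bg_mean[:, None]

    subtype_idx = np.repeat(np.arange(3), ns)
    base = means[:, subtype_idx]
    noise = rng.standard_normal(base.shape)

    # batches interleave within subtype so every batch sees every subtype
    batch_idx = np.concatenate([np.arange(k) % config.n_batches for k in ns])
    if config.n_batches > 1:
        gamma = rng.normal(0.0, config.batch_shift_sd, (len(genes), config.n_batches))
        delta = np.exp(rng.normal(0.0, config.batch_scale_sd, (len(genes), config.n_batches)))
        values = base + gamma[:, batch_idx] + delta[:, batch_idx] * config.noise_sd * noise
    else:
        values = base + config.noise_sd * noise

    matrix = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=sample_ids)
    manifest = {
        "config": {
            "n_samples_per_subtype": list(ns),
            "n_genes": config.n_genes,
            "n_rtk_like": config.n_rtk_like,
            "n_marker_genes_per_block": n_block,
            "marker_effect": config.marker_effect,
            "noise_sd": config.noise_sd,
            "silenced_mean": config.silenced_mean,
            "expressed_mean": config.expressed_mean,
            "expressed_fraction": config.expressed_fraction,
            "n_batches": config.n_batches,
            "batch_shift_sd": config.batch_shift_sd,
            "batch_scale_sd": config.batch_scale_sd,
            "seed": config.seed,
        },
        "rtk_genes": list(RTK_GENES),
        "rtk_panel": list(RTK_GENES) + rtk_like,
        "invasive_program_genes": inv_program,
        "background_expressed": {g: bool(s) for g, s in zip(bg_genes, bg_state)},
    }
    return SimulatedDataset(
        matrix=matrix,
        true_subtype=pd.Series(subtype, index=sample_ids, name="subtype"),
        true_batch=pd.Series(
            [f"B{b + 1}" for b in batch_idx], index=sample_ids, name="batch"
        ),
        true_marker_sets={s: list(v) for s, v in marker_sets.items()},
        truth_manifest=manifest,
    )


@dataclass
class DoseResponseSimConfig:
    """Parameters of a single-drug dose-response simulation."""

    model: Literal["four_pl", "median_effect"] = "median_effect"
    dm: float = 1.0  # median-effect dose Dm, or the 4PL IC50 (uM)
    hill_m: float = 1.0
    bottom: float = 0.0  # four_pl only
    top: float = 1.0  # four_pl only
    doses: Sequence[float] = DEFAULT_DOSES
    noise_sd: float = 0.0
    replicates: int = 3
    seed: int = 0

    def validate(self) -> None:
        doses = np.asarray(self.doses, float)
        if doses.ndim != 1 or len(doses) == 0:
            raise ValueError("doses must be a non-empty 1-D sequence")
        if np.any(doses <= 0):
            raise ValueError("doses must be strictly positive")
        if np.any(np.diff(doses) <= 0):
            raise ValueError("doses must be sorted strictly increasing")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.dm <= 0 or self.hill_m <= 0:
            raise ValueError("Dm/IC50 and hill_m must be > 0")
        if self.model not in ("four_pl", "median_effect"):
            raise ValueError(f"unknown model {self.model!r}")


def _clean_viability(config: DoseResponseSimConfig, doses: np.ndarray) -> np.ndarray:
    if config.model == "median_effect":
        fa = 1.0 / (1.0 + (config.dm / doses) ** config.hill_m)
        return 1.0 - fa
    return config.bottom + (config.top - config.bottom) / (
        1.0 + (doses / config.dm) ** config.hill_m
    )


def generate_dose_response(config: DoseResponseSimConfig) -> pd.DataFrame:
    """Simulate a single-drug viability table (columns dose, replicate, viability)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    doses = np.asarray(config.doses, float)
    clean = _clean_viability(config, doses)
    rows = []
    for rep in range(1, config.replicates + 1):
        v = clean + rng.normal(0.0, config.noise_sd, len(doses)) if config.noise_sd else clean
        v = np.clip(v, 0.0, 1.2)
        for d, y in zip(doses, v):
            rows.append((d, rep, float(y)))
    return pd.DataFrame(rows, columns=["dose", "replicate", "viability"])


def _dx(dm: float, m: float, fa: float) -> float:
    return dm * (fa / (1.0 - fa)) ** (1.0 / m)


def _loewe_fa(d1: float, d2: float, a: DoseResponseSimConfig, b: DoseResponseSimConfig,
              factor: float) -> float:
    """Fraction affected of a Loewe-consistent combination with potency factor."""

    def g(fa: float) -> float:
        return d1 / factor / _dx(a.dm, a.hill_m, fa) + d2 / factor / _dx(
            b.dm, b.hill_m, fa
        ) - 1.0

    lo, hi = 1e-9, 1.0 - 1e-9
    if g(lo) <= 0:
        return lo
    if g(hi) >= 0:
        return hi
    return brentq(g, lo, hi, xtol=1e-12)


def generate_combination(
    config_a: DoseResponseSimConfig,
    config_b: DoseResponseSimConfig,
    interaction: Literal["sham", "loewe_additive", "synergy_factor"] = "loewe_additive",
    synergy_factor: float = 1.0,
    dose_pairs: Sequence[tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Simulate a two-drug combination table (columns d1, d2, replicate, viability).

    ``sham``: drug B is drug A relabeled; the combination responds as drug A at
    the summed dose.  ``loewe_additive``: the pair satisfies Loewe additivity
    exactly (combination index 1).  ``synergy_factor``: the dose needed for any
    effect level is ``synergy_factor`` times the Loewe-additive requirement, so
    the combination index equals the factor by construction.
    """
    config_a.validate()
    config_b.validate()
    if config_a.model != "median_effect" or config_b.model != "median_effect":
        raise ValueError("combination generation requires median_effect models")
    if interaction == "sham":
        config_b = config_a
        factor = 1.0
    elif interaction == "loewe_additive":
        factor = 1.0
    elif interaction == "synergy_factor":
        if synergy_factor <= 0:
            raise ValueError("synergy_factor must be > 0")
        factor = synergy_factor
    else:
        raise ValueError(f"unknown interaction {interaction!r}")

    if dose_pairs is None:
        dose_pairs = [(d / 2.0, d / 2.0) for d in config_a.doses]
    rng = np.random.default_rng(config_a.seed + 1_000_003 * config_b.seed + 17)
    noise_sd = max(config_a.noise_sd, config_b.noise_sd)
    rows = []
    for d1, d2 in dose_pairs:
        fa = _loewe_fa(d1, d2, config_a, config_b, factor)
        clean = 1.0 - fa
        for rep in range(1, config_a.replicates + 1):
            v = clean + (rng.normal(0.0, noise_sd) if noise_sd else 0.0)
            rows.append((d1, d2, rep, float(np.clip(v, 0.0, 1.2))))
    return pd.DataFrame(rows, columns=["d1", "d2", "replicate", "viability"])
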