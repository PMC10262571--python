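"""Trait architecture: QTL effects, true breeding values, phenotypes.

QTL allele-substitution effects are gamma-distributed in magnitude
(shape 0.4 by default) with random sign, then rescaled by a single scalar
so the realized founder breeding-value variance equals sigma_g^2 =
h^2 * sigma_p^2 -- the QTL explain 100% of the genetic variance.

Two true-breeding-value modes are supported:

* ``recursive`` -- g_i = g_s/2 + g_d/2 + w_i with the Mendelian sampling
  term w_i ~ N(0, sigma_w^2), sigma_w^2 = (1 - f_s) sigma_a^2 / 4 +
  (1 - f_d) sigma_a^2 / 4, where f_s, f_d are the parents' pedigree
  inbreeding coefficients and sigma_a^2 is fixed at the base-generation
  genetic variance.
* ``genomic`` -- g_i is the dosage-weighted QTL sum, centred so the
  founder cohort mean is zero.  Used for internal consistency checks and
  for real-data entry points.

Phenotypes follow y = mu + g + e with e ~ N(0, sigma_e^2) drawn fresh in
every generation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import GenomeMap
from .population import Population
from .rng import as_rng

__all__ = [
    "TraitArchitecture",
    "sample_qtl_effects",
    "true_bv_genomic",
    "true_bv_recursive",
    "mendelian_sampling_variance",
    "phenotype",
]


@dataclass(frozen=True)
class TraitArchitecture:
    """Additive genetic architecture of one simulated trait."""

    qtl_effects: np.ndarray  # allele-substitution effect per QTL, rescaled
    mu: float  # population mean
    sigma_p2: float  # phenotypic variance
    h2: float  # narrow-sense heritability
    gamma_shape: float
    founder_offset: float  # founder mean of the raw QTL sum; centres g at 0

    def __post_init__(self) -> None:
        if not 0 <= self.h2 <= 1:
            raise ValueError("heritability must lie in [0, 1]")
        if self.sigma_p2 < 0:
            raise ValueError("phenotypic variance must be non-negative")

    @property
    def sigma_g2(self) -> float:
        return self.h2 * self.sigma_p2

    @property
    def sigma_e2(self) -> float:
        # complement of sigma_g2, so the two always sum to sigma_p2 exactly
        return self.sigma_p2 - self.sigma_g2

    @property
    def sigma_a2(self) -> float:
        """Base-generation additive variance used in the Mendelian sampling term."""
        return self.sigma_g2


def sample_qtl_effects(
    gmap: GenomeMap,
    founders: Population,
    h2: float,
    sigma_p2: float = 1000.0,
    gamma_shape: float = 0.4,
    mu: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> TraitArchitecture:
    """Draw and rescale QTL effects against the founder cohort.

    Magnitudes are Gamma(shape, scale=1), signs independent fair coin
    flips.  The rescaling makes the population variance of the founder QTL
    sums exactly h2 * sigma_p2; h2 = 0 degenerates to all-zero effects.
    Raises if every QTL is monomorphic in the founders (nothing to rescale).
    """
    rng = as_rng(seed)
    n_qtl = gmap.n_qtl
    raw = rng.gamma(gamma_shape, 1.0, size=n_qtl)
    raw *= rng.choice(np.array([-1.0, 1.0]), size=n_qtl)
    q_dosage = founders.dosages(gmap.qtl_indices).astype(np.float64)
    g_raw = q_dosage @ raw
    var_raw = float(g_raw.var())
    if h2 == 0:
        scale = 0.0
    else:
        if var_raw == 0:
            raise ValueError("all QTL are monomorphic in the founders; cannot rescale")
        scale = np.sqrt(h2 * sigma_p2 / var_raw)
    effects = raw * scale
    return TraitArchitecture(
        qtl_effects=effects,
        mu=float(mu),
        sigma_p2=float(sigma_p2),
        h2=float(h2),
        gamma_shape=float(gamma_shape),
        founder_offset=float(g_raw.mean() * scale),
    )


def true_bv_genomic(qtl_dosages: np.ndarray, arch: TraitArchitecture) -> np.ndarray:
    """QTL-sum breeding values, centred on the founder cohort mean."""
    d = np.asarray(qtl_dosages, dtype=np.float64)
    return d @ arch.qtl_effects - arch.founder_offset


def mendelian_sampling_variance(f_s, f_d, sigma_a2: float):
    """sigma_w^2 = (1 - f_s) sigma_a^2 / 4 + (1 - f_d) sigma_a^2 / 4."""
    f_s = np.asarray(f_s, dtype=np.float64)
    f_d = np.asarray(f_d, dtype=np.float64)
    if np.any((f_s < 0) | (f_s > 1) | (f_d < 0) | (f_d > 1)):
        raise ValueError("parental inbreeding coefficients must lie in [0, 1]")
    return 0.25 * (1.0 - f_s) * sigma_a2 + 0.25 * (1.0 - f_d) * sigma_a2


def true_bv_recursive(
    g_s,
    g_d,
    f_s,
    f_d,
    sigma_a2: float,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Pedigree-recursive breeding values g = g_s/2 + g_d/2 + w.

    The Mendelian sampling term w is one fresh normal draw per offspring
    with variance reduced by parental inbreeding.  Returns ``(g, w)``.
    """
    rng = as_rng(seed)
    g_s = np.asarray(g_s, dtype=np.float64)
    g_d = np.asarray(g_d, dtype=np.float64)
    var_w = mendelian_sampling_variance(f_s, f_d, sigma_a2)
    w = rng.standard_normal(np.broadcast(g_s, g_d).shape) * np.sqrt(var_w)
    return 0.5 * g_s + 0.5 * g_d + w, w


def phenotype(
    g,
    arch: TraitArchitecture,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Phenotypes y = mu + g + e with fresh residuals e ~ N(0, sigma_e^2)."""
    rng = as_rng(seed)
    g = np.asarray(g, dtype=np.float64)
    e = rng.standard_normal(g.shape) * np.sqrt(arch.sigma_e2)
    return arch.mu + g + e, e
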