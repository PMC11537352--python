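"""Synthetic spatial transcriptomics tissues with known HV/SV gene structure.

The generator emulates the data regime in which highly variable (HV) and
spatially variable (SV) gene selections are genuinely complementary:

* spatially organized *domains* host *localized* cell types, so genes with
  spatial expression patterns (hotspots, gradients, periodic waves) and the
  markers of localized types both carry spatial signal;
* *dispersed* cell types are scattered uniformly over the tissue and are
  distinguishable only through non-spatial marker genes — an SV-only feature
  set cannot separate them;
* pure-noise genes carry neither signal.

Counts are negative binomial (mean mu, dispersion theta, variance
mu + mu^2/theta) with per-cell lognormal library-size factors applied to the
means, which keeps the NB family closed.  Per-gene mean surfaces are stored on
the returned dataset so tests can assert the construction directly.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import io as stio
from .containers import (
    ExpressionMatrix,
    LabelSet,
    SpatialCoords,
    ValidationError,
    _sub_rng,
)

LAYOUTS = ("stripes", "voronoi", "grid")
SV_PATTERNS = ("hotspot", "gradient", "periodic")


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic tissue.

    Defaults describe a small imaging-platform-like dataset: 500 cells in the
    unit square over 4 stripe domains, 4 localized + 3 dispersed cell types
    (30% of cells dispersed), 40 SV-pattern genes, 40 HV marker genes and 80
    noise genes at a base mean of 2 counts.  NB dispersion defaults to
    theta = 100 so null (noise) genes sit at the analytic Pearson-residual
    null; the spatial amplitude is moderate so SV genes are spatially coherent
    without dominating marginal variance.
    """

    n_cells: int = 500
    n_domains: int = 4
    layout: str = "stripes"
    n_localized_types: int = 4
    n_dispersed_types: int = 3
    dispersed_fraction: float = 0.3
    n_sv_genes: int = 40
    sv_patterns: tuple = SV_PATTERNS
    n_hv_genes: int = 40
    n_noise_genes: int = 80
    marker_log_fold_change: float = float(np.log(3.0))
    sv_amplitude: float = 1.0
    base_mean: float = 2.0
    nb_dispersion: float = 100.0
    libsize_sigma: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.layout not in LAYOUTS:
            raise ValidationError(f"unknown layout {self.layout!r}")
        unknown = set(self.sv_patterns) - set(SV_PATTERNS)
        if unknown:
            raise ValidationError(f"unknown sv patterns {sorted(unknown)}")
        if self.n_localized_types > self.n_domains:
            raise ValidationError("n_localized_types must be <= n_domains")
        if not (0 <= self.dispersed_fraction < 1):
            raise ValidationError("dispersed_fraction must lie in [0, 1)")
        for name in ("n_cells", "n_domains", "n_localized_types",
                     "n_dispersed_types", "n_sv_genes", "n_hv_genes"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if self.n_noise_genes < 0:
            raise ValidationError("n_noise_genes must be >= 0")
        for name in ("marker_log_fold_change", "sv_amplitude", "base_mean",
                     "nb_dispersion"):
            if not getattr(self, name) >= 0:
                raise ValidationError(f"{name} must be non-negative")
        if self.libsize_sigma < 0:
            raise ValidationError("libsize_sigma must be >= 0")


@dataclass
class SyntheticDataset:
    matrix: ExpressionMatrix
    coords: SpatialCoords
    truth: LabelSet
    gene_class: pd.DataFrame  # columns: gene, gene_class, subtype
    mean_surface: np.ndarray  # cells x genes expected counts (incl. library size)
    config: SyntheticConfig
    domains: np.ndarray = field(default=None)

    def write(self, out_dir: str) -> None:
        os.makedirs(out_dir, exist_ok=True)
        stio.write_counts(self.matrix, os.path.join(out_dir, "matrix.mtx"))
        stio.write_coords(self.coords, os.path.join(out_dir, "coords.csv"))
        stio.write_labels(self.truth, os.path.join(out_dir, "labels.csv"))
        self.gene_class.to_csv(os.path.join(out_dir, "gene_class.csv"), index=False)


def generate_tissue(
    config: SyntheticConfig, return_meta: bool = False
) -> tuple[SpatialCoords, np.ndarray] | tuple[SpatialCoords, np.ndarray, dict]:
    """Place cells in the unit square and assign each to a spatial domain.

    ``stripes``/``voronoi`` place cells uniformly at random; ``grid`` uses a
    jittered lattice.  Domains are equal-width vertical bands for ``stripes``
    and ``grid`` and nearest-seed-point regions for ``voronoi``.  With
    ``return_meta`` the layout internals (e.g. Voronoi seed points) are
    returned as a third element for white-box checks.
    """
    if config.n_domains > config.n_cells:
        raise ValidationError("more domains than cells")
    rng = _sub_rng(config.seed, 1)
    n = config.n_cells
    if config.layout == "grid":
        m = int(np.ceil(np.sqrt(n)))
        gx, gy = np.meshgrid((np.arange(m) + 0.5) / m, (np.arange(m) + 0.5) / m)
        pts = np.column_stack([gx.ravel(), gy.ravel()])[:n]
        pts = pts + rng.uniform(-0.4 / m, 0.4 / m, size=pts.shape)
        x, y = pts[:, 0], pts[:, 1]
    else:
        x = rng.uniform(0.0, 1.0, size=n)
        y = rng.uniform(0.0, 1.0, size=n)
    meta: dict = {"voronoi_seeds": None}
    if config.layout == "voronoi":
        seeds = rng.uniform(0.0, 1.0, size=(config.n_domains, 2))
        d2 = (x[:, None] - seeds[None, :, 0]) ** 2 + (y[:, None] - seeds[None, :, 1]) ** 2
        domains = np.argmin(d2, axis=1)
        meta["voronoi_seeds"] = seeds
    else:
        domains = np.minimum(
            (x * config.n_domains).astype(int), config.n_domains - 1
        )
    cell_ids = np.array([f"cell{i:05d}" for i in range(n)], dtype=str)
    coords = SpatialCoords(cell_ids, x, y)
    if return_meta:
        return coords, domains, meta
    return coords, domains


def assign_cell_types(domains: np.ndarray, config: SyntheticConfig) -> LabelSet:
    """Assign localized types per domain, then scatter dispersed types.

    Localized type ``L{t}`` is tied to the domains ``d`` with
    ``d % n_localized_types == t``.  A ``dispersed_fraction`` of cells, sampled
    uniformly over the whole tissue, is reassigned among the dispersed types
    ``D{t}`` independent of location.
    """
    rng = _sub_rng(config.seed, 2)
    domains = np.asarray(domains, dtype=int)
    n = domains.size
    labels = np.array(
        [f"L{d % config.n_localized_types}" for d in domains], dtype=object
    )
    n_disp = int(round(config.dispersed_fraction * n))
    if n_disp > 0:
        chosen = rng.choice(n, size=n_disp, replace=False)
        disp_types = rng.integers(0, config.n_dispersed_types, size=n_disp)
        labels[chosen] = [f"D{t}" for t in disp_types]
    cell_ids = np.array([f"cell{i:05d}" for i in range(n)], dtype=str)
    return LabelSet(cell_ids, labels.astype(str))


def _pattern_surface(kind: str, x: np.ndarray, y: np.ndarray, rng) -> np.ndarray:
    """A spatial modulation f(x, y) in [0, 1]."""
    if kind == "hotspot":
        cx, cy = rng.uniform(0.2, 0.8, size=2)
        sigma = 0.15
        return np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / (2 * sigma**2))
    if kind == "gradient":
        angle = rng.uniform(0, 2 * np.pi)
        proj = x * np.cos(angle) + y * np.sin(angle)
        lo, hi = proj.min(), proj.max()
        return (proj - lo) / (hi - lo) if hi > lo else np.zeros_like(proj)
    if kind == "periodic":
        phase = rng.uniform(0, 2 * np.pi)
        return 0.5 * (1 + np.sin(2 * np.pi * 2 * x + phase))
    raise ValidationError(f"unknown sv pattern {kind!r}")


def generate_expression(
    truth: LabelSet, coords: SpatialCoords, config: SyntheticConfig
) -> tuple[ExpressionMatrix, pd.DataFrame, np.ndarray]:
    """Draw NB counts from per-gene mean surfaces.

    Returns ``(matrix, gene_class, mean_surface)``; the mean surface includes
    the library-size factors and is what the counts were actually drawn from.
    """
    rng = _sub_rng(config.seed, 3)
    n = len(truth.cell_ids)
    x, y = coords.x, coords.y
    types = truth.labels
    all_types = list(pd.unique(types))

    gene_ids, gclass, subtype = [], [], []
    mu = []
    patterns = list(config.sv_patterns)
    for g in range(config.n_sv_genes):
        kind = patterns[g % len(patterns)]
        f = _pattern_surface(kind, x, y, rng)
        mu.append(config.base_mean * np.exp(config.sv_amplitude * (f - 0.5)))
        gene_ids.append(f"sv{g:03d}")
        gclass.append("sv_pattern")
        subtype.append(kind)
    # Markers attach to the dispersed types: they are the types carrying no
    # spatial signal, so HV markers are the only route to separating them,
    # while localized types are resolvable through the spatial patterns.
    # With no dispersed cells present, markers fall back to localized types.
    marker_types = [t for t in all_types if t.startswith("D")] or all_types
    for g in range(config.n_hv_genes):
        t = marker_types[g % len(marker_types)]
        m = np.full(n, config.base_mean, dtype=float)
        m[types == t] *= np.exp(config.marker_log_fold_change)
        mu.append(m)
        gene_ids.append(f"hv{g:03d}")
        gclass.append("hv_marker")
        subtype.append(t)
    for g in range(config.n_noise_genes):
        mu.append(np.full(n, config.base_mean, dtype=float))
        gene_ids.append(f"ns{g:03d}")
        gclass.append("noise")
        subtype.append("")
    mu = np.column_stack(mu)

    if config.libsize_sigma > 0:
        lib = rng.lognormal(mean=0.0, sigma=config.libsize_sigma, size=n)
        lib /= lib.mean()
    else:
        lib = np.ones(n)
    mu = mu * lib[:, None]

    theta = config.nb_dispersion
    if np.isfinite(theta):
        lam = rng.gamma(shape=theta, scale=mu / theta)
    else:
        lam = mu
    counts = rng.poisson(lam).astype(float)

    matrix = ExpressionMatrix(counts, truth.cell_ids.copy(), np.asarray(gene_ids), "raw")
    gene_class = pd.DataFrame(
        {"gene": gene_ids, "gene_class": gclass, "subtype": subtype}
    )
    return matrix, gene_class, mu


def generate_dataset(config: SyntheticConfig | None = None, **overrides) -> SyntheticDataset:
    """Compose tissue layout, cell-type assignment and expression generation."""
    if config is None:
        config = SyntheticConfig(**overrides)
    elif overrides:
        config = SyntheticConfig(**{**asdict(config), **overrides})
    coords, domains = generate_tissue(config)
    truth = assign_cell_types(domains, config)
    matrix, gene_class, mu = generate_expression(truth, coords, config)
    return SyntheticDataset(
        matrix=matrix,
        coords=coords,
        truth=truth,
        gene_class=gene_class,
        mean_surface=mu,
        config=config,
        domains=domains,
    )
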