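"""Additive mutation-load model with GERP-binned selection coefficients.

Each site conserved enough to score (GERP > 2) receives a selection
coefficient by deleteriousness bin — mild (2, 4] -> s = -4.5e-4, moderate
(4, 6] -> s = -4.5e-3, critical (6, inf) -> s = -1e-2 — and contributes a
load L = 2shf(1-f) + sf^2 at derived allele frequency f.  With the additive
dominance h = 0.5 this collapses to L = s*f.  Loads are summed or
SNP-averaged over gene sets per population.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd


@dataclasses.dataclass(frozen=True)
class GerpBinConfig:
    """Deleteriousness bins (lower-exclusive, upper-inclusive) and coefficients."""

    bounds: tuple[float, ...] = (2.0, 4.0, 6.0)
    coefficients: tuple[float, ...] = (-4.5e-4, -4.5e-3, -1e-2)
    h: float = 0.5

    def __post_init__(self) -> None:
        if len(self.coefficients) != len(self.bounds):
            raise ValueError("one coefficient per bin lower bound")
        if list(self.bounds) != sorted(self.bounds):
            raise ValueError("bin bounds must be increasing")
        if any(s >= 0 for s in self.coefficients):
            raise ValueError("selection coefficients must be negative")
        if not (0 <= self.h <= 1):
            raise ValueError("dominance h must be in [0, 1]")


DEFAULT_BINS = GerpBinConfig()


def gerp_to_s(gerp: float, cfg: GerpBinConfig = DEFAULT_BINS) -> float | None:
    """Selection coefficient for a GERP score; None below the lowest bin.

    Bin membership is (lower, upper]: a score exactly at an internal bound
    belongs to the lower bin.
    """
    if np.isnan(gerp) or gerp <= cfg.bounds[0]:
        return None
    for lo, hi, s in zip(
        cfg.bounds, list(cfg.bounds[1:]) + [np.inf], cfg.coefficients
    ):
        if lo < gerp <= hi:
            return s
    return None  # unreachable


def site_load(f: float | np.ndarray, s: float, h: float = 0.5) -> float | np.ndarray:
    """Per-site additive load L = 2shf(1-f) + sf^2 at derived AF f."""
    f = np.asarray(f, dtype=float)
    if (f < 0).any() or (f > 1).any():
        raise ValueError("derived allele frequency must be in [0, 1]")
    L = 2 * s * h * f * (1 - f) + s * f**2
    return float(L) if L.ndim == 0 else L


def site_load_table(
    freqs: pd.DataFrame,
    gerp: pd.Series,
    populations: Sequence[str],
    cfg: GerpBinConfig = DEFAULT_BINS,
) -> pd.DataFrame:
    """Per-site s and load per population.

    ``freqs`` is indexed by site_id with one derived-AF column per
    population; ``gerp`` maps site_id -> GERP score.  Sites without a GERP
    score above the lowest bound are excluded.
    """
    table = freqs[list(populations)].copy()
    table["gerp"] = gerp.reindex(table.index)
    table["s"] = [
        np.nan if (v := gerp_to_s(g, cfg)) is None else v for g in table["gerp"]
    ]
    table = table.dropna(subset=["s"])
    for pop in populations:
        table[f"L_{pop}"] = site_load_vec(
            table[pop].to_numpy(), table["s"].to_numpy(), cfg.h
        )
    return table


def site_load_vec(f: np.ndarray, s: np.ndarray, h: float = 0.5) -> np.ndarray:
    """Vectorized per-site load with site-specific coefficients."""
    f = np.asarray(f, dtype=float)
    s = np.asarray(s, dtype=float)
    return 2 * s * h * f * (1 - f) + s * f**2


def aggregate_load(
    table: pd.DataFrame, population: str, gene_set: Sequence[str] | None = None
) -> dict:
    """Total and mean-per-SNP load over a gene set's sites for one population.

    ``gene_set`` is a collection of site_ids (None = all scored sites).
    """
    col = f"L_{population}"
    if col not in table.columns:
        raise KeyError(f"no load column for population {population!r}")
    sub = table if gene_set is None else table.loc[table.index.intersection(gene_set)]
    sub = sub[np.isfinite(sub[col])]
    if len(sub) == 0:
        raise ValueError("no eligible sites in the requested set")
    total = float(sub[col].sum())
    return {"population": population, "n_sites": len(sub), "total": total, "mean": total / len(sub)}
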