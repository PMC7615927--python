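"""Species-level design table: biogeographic covariates, response transform,
standardization.

The comparative model explains per-species nucleotide diversity with species
traits (body size, vision, maternal care) and biogeography (mean latitude of
the sequenced localities, latitudinal range of the species, average
great-circle distance among sequence localities).  This module turns raw
coordinates and traits into the standardized design matrices used by
:class:`macrodiv.betareg.BetaRegression`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EARTH_RADIUS_KM",
    "haversine_km",
    "mean_pairwise_distance",
    "mean_latitude",
    "adjust_zeros",
    "DesignMatrix",
    "assemble_design",
    "MEAN_COVARIATES",
    "CONTINUOUS_COVARIATES",
    "BINARY_COVARIATES",
]

#: IUGG mean Earth radius.
EARTH_RADIUS_KM = 6371.0088

#: mean-submodel covariates, in reporting order
CONTINUOUS_COVARIATES = ("mean_latitude", "mean_geo_distance", "lat_range", "body_size")
BINARY_COVARIATES = ("vision", "maternal_care")
MEAN_COVARIATES = CONTINUOUS_COVARIATES + BINARY_COVARIATES


def haversine_km(p1: Sequence[float], p2: Sequence[float]) -> float:
    """Great-circle distance in km between two (lat, lon) points in degrees."""
    lat1, lon1 = float(p1[0]), float(p1[1])
    lat2, lon2 = float(p2[0]), float(p2[1])
    for lat, lon in ((lat1, lon1), (lat2, lon2)):
        if not (np.isfinite(lat) and np.isfinite(lon)):
            raise ValueError("non-finite coordinate")
        if abs(lat) > 90 or abs(lon) > 180:
            raise ValueError(f"coordinate out of range: ({lat}, {lon})")
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(lon2 - lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0))))


def mean_pairwise_distance(coords: Sequence[Sequence[float]]) -> float:
    """Mean haversine distance over all unordered pairs of sequence localities.

    Duplicate localities contribute zero-distance pairs (averaging is over
    sequence records, not unique places).  A single record gives 0.
    """
    coords = list(coords)
    if not coords:
        raise ValueError("empty coordinate list")
    m = len(coords)
    if m == 1:
        return 0.0
    total = 0.0
    for i in range(m):
        for j in range(i + 1, m):
            total += haversine_km(coords[i], coords[j])
    return total / (m * (m - 1) / 2)


def mean_latitude(coords: Sequence[Sequence[float]], signed: bool = True) -> float:
    """Arithmetic mean latitude of the sequence localities.

    Signed by default (southern hemisphere negative), which preserves the
    hemispheric contrast; ``signed=False`` averages absolute latitudes.
    """
    coords = list(coords)
    if not coords:
        raise ValueError("empty coordinate list")
    lats = np.asarray([c[0] for c in coords], dtype=float)
    if not signed:
        lats = np.abs(lats)
    return float(lats.mean())


def adjust_zeros(
    y: np.ndarray | Sequence[float],
    n_obs: int | None = None,
    mode: Literal["sv_zeros", "sv_all", "epsilon"] = "sv_zeros",
    eps: float = 1e-4,
) -> np.ndarray:
    """Move exact zeros of a proportion response strictly inside (0, 1).

    Beta regression cannot accommodate boundary values, so zero diversity
    estimates are replaced by a small value.  ``sv_zeros`` (default) applies
    the Smithson–Verkuilen shrinkage value (y*(n-1)+0.5)/n at y=0 only, i.e.
    zeros become 0.5/n; ``sv_all`` applies the full transform to every
    observation; ``epsilon`` replaces zeros by ``eps``.
    """
    y = np.asarray(y, dtype=float)
    if np.any((y < 0) | (y >= 1)):
        raise ValueError("response values must lie in [0, 1)")
    if mode in ("sv_zeros", "sv_all"):
        if n_obs is None:
            n_obs = y.size
        if n_obs < 2:
            raise ValueError("n_obs must be >= 2 for the shrinkage transform")
        if mode == "sv_zeros":
            out = np.where(y == 0, 0.5 / n_obs, y)
        else:
            out = (y * (n_obs - 1) + 0.5) / n_obs
    elif mode == "epsilon":
        if not 0 < eps < 1:
            raise ValueError("eps must be in (0, 1)")
        out = np.where(y == 0, eps, y)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if np.any((out <= 0) | (out >= 1)):
        raise ValueError("adjusted response not strictly inside (0, 1)")
    return out


@dataclass
class DesignMatrix:
    """Row-aligned response and submodel matrices with standardization constants.

    ``X`` is the mean-submodel matrix (intercept first, z-scored continuous
    covariates, 0/1 dummies); ``Z`` is the precision-submodel matrix
    (intercept, z-scored number of sequences).  ``center``/``scale`` map each
    standardized column back to its raw units.
    """

    y: np.ndarray
    X: np.ndarray
    Z: np.ndarray
    x_names: list[str]
    z_names: list[str]
    species_id: list[str]
    family: list[str]
    center: dict[str, float] = field(default_factory=dict)
    scale: dict[str, float] = field(default_factory=dict)
    raw: pd.DataFrame | None = None

    def standardize_value(self, column: str, raw_value: np.ndarray) -> np.ndarray:
        if column in self.center:
            return (np.asarray(raw_value, float) - self.center[column]) / self.scale[column]
        return np.asarray(raw_value, float)

    def with_columns(self, extra: pd.DataFrame) -> "DesignMatrix":
        """Return a copy with extra (already-scaled) columns appended to X."""
        X = np.column_stack([self.X, extra.to_numpy(dtype=float)])
        return DesignMatrix(
            y=self.y,
            X=X,
            Z=self.Z,
            x_names=self.x_names + list(extra.columns),
            z_names=list(self.z_names),
            species_id=list(self.species_id),
            family=list(self.family),
            center=dict(self.center),
            scale=dict(self.scale),
            raw=self.raw,
        )

    def subset(self, mask: np.ndarray) -> "DesignMatrix":
        mask = np.asarray(mask, bool)
        return DesignMatrix(
            y=self.y[mask],
            X=self.X[mask],
            Z=self.Z[mask],
            x_names=list(self.x_names),
            z_names=list(self.z_names),
            species_id=[s for s, k in zip(self.species_id, mask) if k],
            family=[f for f, k in zip(self.family, mask) if k],
            center=dict(self.center),
            scale=dict(self.scale),
            raw=self.raw.loc[mask].reset_index(drop=True) if self.raw is not None else None,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.x_names)
        df.insert(0, "species_id", self.species_id)
        df["y"] = self.y
        for name in self.z_names[1:]:
            df[f"precision_{name}"] = self.Z[:, self.z_names.index(name)]
        return df


def assemble_design(
    records: pd.DataFrame,
    standardize: bool = True,
    zero_mode: Literal["sv_zeros", "sv_all", "epsilon"] = "sv_zeros",
    eps: float = 1e-4,
    response_column: str = "pi",
) -> DesignMatrix:
    """Build the design from a species table.

    ``records`` needs one row per species with columns: species_id, family,
    body_size, vision, maternal_care, lat_range, mean_latitude,
    mean_geo_distance, n_sequences and the response column (raw nucleotide
    diversity, zeros permitted — they are adjusted here).
    """
    required = [
        "species_id",
        "family",
        "n_sequences",
        response_column,
        *MEAN_COVARIATES,
    ]
    missing_cols = [c for c in required if c not in records.columns]
    if missing_cols:
        raise ValueError(f"species table missing columns: {missing_cols}")
    bad = records[required].isna().any(axis=1)
    if bad.any():
        raise ValueError(
            "missing covariate values for species: "
            + ", ".join(records.loc[bad, "species_id"].astype(str))
        )
    n = len(records)
    n_cols = 1 + len(MEAN_COVARIATES)
    if n < n_cols + 2:
        raise ValueError(f"need at least {n_cols + 2} species, got {n}")
    if (records["n_sequences"] < 3).any():
        raise ValueError("all species must have n_sequences >= 3 (inclusion filter)")
    if (records["body_size"] <= 0).any():
        raise ValueError("body_size must be positive")

    y = adjust_zeros(
        records[response_column].to_numpy(dtype=float), n_obs=n, mode=zero_mode, eps=eps
    )

    center: dict[str, float] = {}
    scale: dict[str, float] = {}
    cols = [np.ones(n)]
    names = ["intercept"]
    for name in CONTINUOUS_COVARIATES:
        v = records[name].to_numpy(dtype=float)
        if standardize:
            sd = v.std(ddof=1)
            if sd == 0:
                raise ValueError(f"covariate '{name}' has zero variance; cannot standardize")
            center[name], scale[name] = float(v.mean()), float(sd)
            v = (v - v.mean()) / sd
        cols.append(v)
        names.append(name)
    for name in BINARY_COVARIATES:
        v = records[name].to_numpy(dtype=float)
        if not np.isin(v, (0.0, 1.0)).all():
            raise ValueError(f"binary covariate '{name}' must be coded 0/1")
        cols.append(v)
        names.append(name)
    X = np.column_stack(cols)

    nseq = records["n_sequences"].to_numpy(dtype=float)
    if standardize:
        sd = nseq.std(ddof=1)
        if sd == 0:
            raise ValueError("covariate 'n_sequences' has zero variance; cannot standardize")
        center["n_sequences"], scale["n_sequences"] = float(nseq.mean()), float(sd)
        nseq = (nseq - nseq.mean()) / sd
    Z = np.column_stack([np.ones(n), nseq])

    return DesignMatrix(
        y=y,
        X=X,
        Z=Z,
        x_names=names,
        z_names=["intercept", "n_sequences"],
        species_id=records["species_id"].astype(str).tolist(),
        family=records["family"].astype(str).tolist(),
        center=center,
        scale=scale,
        raw=records.reset_index(drop=True),
    )
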