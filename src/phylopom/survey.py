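"""Detection histories, site covariates, collinearity screening, and
sampling-effort arithmetic for a two-method survey design.

Detection data are season-collapsed: for each species, site, and method the
dataset stores the number of seasons surveyed (N) and the number of seasons
with at least one detection (Y). A species enters a method's likelihood iff
any row for that species/method exists in the input (the method mask).
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "METHODS",
    "DetectionDataset",
    "SiteCovariates",
    "CollinearityReport",
    "EffortRecord",
    "load_detections",
    "collinearity_screen",
    "mistnet_effort",
    "mistnet_night_effort",
    "aru_effort",
    "aru_files",
]

METHODS = ("mist_net", "aru")


@dataclass
class DetectionDataset:
    """Per-method season-level detection counts with method masks.

    Arrays are indexed (method, site, species) for Y, (method, site) for N,
    and (method, species) for the mask.
    """

    species: list
    sites: list
    Y: np.ndarray
    N: np.ndarray
    mask: np.ndarray
    methods: tuple = METHODS

    def __post_init__(self):
        self.species = list(self.species)
        self.sites = list(self.sites)
        self.Y = np.asarray(self.Y, dtype=np.int64)
        self.N = np.asarray(self.N, dtype=np.int64)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.validate()

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def validate(self) -> None:
        M, I, K = len(self.methods), self.n_sites, self.n_species
        if self.Y.shape != (M, I, K):
            raise ValueError(f"Y shape {self.Y.shape} != {(M, I, K)}")
        if self.N.shape != (M, I):
            raise ValueError(f"N shape {self.N.shape} != {(M, I)}")
        if self.mask.shape != (M, K):
            raise ValueError(f"mask shape {self.mask.shape} != {(M, K)}")
        if (self.N < 0).any():
            raise ValueError("seasons surveyed must be non-negative")
        if (self.Y < 0).any():
            raise ValueError("seasons detected must be non-negative")
        if (self.Y > self.N[:, :, None]).any():
            raise ValueError("seasons detected exceeds seasons surveyed")
        if (self.Y[~self.mask.astype(bool)[:, None, :].repeat(I, axis=1)] != 0).any():
            raise ValueError("non-zero detections for a masked-out species/method")
        if not (self.N > 0).any(axis=0).all():
            raise ValueError("every site needs at least one method with N > 0")
        if not self.mask.any(axis=0).all():
            raise ValueError("every species must be scored by at least one method")

    @property
    def detected_any(self) -> np.ndarray:
        """(site, species) boolean: any detection by any applicable method."""
        return (self.Y > 0).any(axis=0)

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DetectionDataset":
        required = ["species", "site", "method", "seasons_surveyed", "seasons_detected"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"detection table missing columns: {missing}")
        bad = sorted(set(df["method"]) - set(METHODS))
        if bad:
            raise ValueError(f"unknown method strings: {bad} (expected {METHODS})")
        over = df[df["seasons_detected"] > df["seasons_surveyed"]]
        if len(over):
            row = over.iloc[0]
            raise ValueError(
                f"seasons_detected > seasons_surveyed for species "
                f"{row['species']!r} site {row['site']!r} method {row['method']!r}"
            )
        species = list(dict.fromkeys(df["species"].astype(str)))
        sites = list(dict.fromkeys(df["site"].astype(str)))
        M, I, K = len(METHODS), len(sites), len(species)
        Y = np.zeros((M, I, K), dtype=np.int64)
        N = np.zeros((M, I), dtype=np.int64)
        mask = np.zeros((M, K), dtype=bool)
        sp_idx = {s: k for k, s in enumerate(species)}
        site_idx = {s: i for i, s in enumerate(sites)}
        m_idx = {m: j for j, m in enumerate(METHODS)}
        seen_N: dict = {}
        for _, row in df.iterrows():
            m = m_idx[row["method"]]
            i = site_idx[str(row["site"])]
            k = sp_idx[str(row["species"])]
            n_sur = int(row["seasons_surveyed"])
            key = (m, i)
            if key in seen_N and seen_N[key] != n_sur:
                raise ValueError(
                    f"inconsistent seasons_surveyed for site {row['site']!r} "
                    f"method {row['method']!r}: {seen_N[key]} vs {n_sur}"
                )
            seen_N[key] = n_sur
            N[m, i] = n_sur
            Y[m, i, k] = int(row["seasons_detected"])
            mask[m, k] = True
        return cls(species, sites, Y, N, mask)

    @classmethod
    def from_csv(cls, path) -> "DetectionDataset":
        return cls.from_frame(pd.read_csv(path))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, sp in enumerate(self.species):
            for m, method in enumerate(self.methods):
                if not self.mask[m, k]:
                    continue
                for i, site in enumerate(self.sites):
                    rows.append(
                        dict(species=sp, site=site, method=method,
                             seasons_surveyed=int(self.N[m, i]),
                             seasons_detected=int(self.Y[m, i, k]))
                    )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def load_detections(path) -> DetectionDataset:
    """Load a long-format detection CSV (see :class:`DetectionDataset`)."""
    return DetectionDataset.from_csv(path)


COVARIATE_COLUMNS = ("elevation", "temperature", "precipitation", "forest_cover")


@dataclass
class SiteCovariates:
    """Site-level environmental covariates with optional z-score standardization.

    Standardization uses the population SD of the supplied sites and keeps
    the original columns for back-transformation.
    """

    frame: pd.DataFrame
    standardized: tuple = ()
    originals: pd.DataFrame | None = None

    def __post_init__(self):
        missing = [c for c in COVARIATE_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"covariate table missing columns: {missing}")
        self.standardized = tuple(self.standardized)

    @property
    def sites(self) -> list:
        return list(self.frame.index)

    @classmethod
    def from_csv(cls, path) -> "SiteCovariates":
        df = pd.read_csv(path)
        if "site" not in df.columns:
            raise ValueError("covariates CSV must have a 'site' column")
        df["site"] = df["site"].astype(str)
        return cls(df.set_index("site"))

    def to_csv(self, path) -> None:
        self.frame.rename_axis("site").to_csv(path)

    def standardize(self, columns=COVARIATE_COLUMNS) -> "SiteCovariates":
        out = self.frame.copy()
        for c in columns:
            x = out[c].to_numpy(dtype=float)
            if np.unique(x).size < 2:
                raise ValueError(f"covariate {c!r} is constant; cannot standardize")
            out[c] = (x - x.mean()) / x.std()  # population SD
        originals = self.originals if self.originals is not None else self.frame.copy()
        return SiteCovariates(out, tuple(columns), originals)

    def matrix(self, names) -> np.ndarray:
        return self.frame[list(names)].to_numpy(dtype=float)


@dataclass
class CollinearityReport:
    pearson_r: pd.DataFrame
    vif: pd.Series

    def to_frame(self) -> pd.DataFrame:
        out = self.pearson_r.copy()
        out["VIF"] = self.vif
        return out


def collinearity_screen(cov: SiteCovariates, names=("temperature", "precipitation", "forest_cover")) -> CollinearityReport:
    """Pairwise Pearson r and per-variable VIF for the named covariates.

    VIF_v = 1 / (1 - R^2) from OLS of v on the remaining variables; perfect
    collinearity is flagged as +inf rather than raised.
    """
    names = list(names)
    X = cov.matrix(names)
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 sites for a collinearity screen")
    r = pd.DataFrame(np.corrcoef(X.T), index=names, columns=names)
    vifs = {}
    for j, name in enumerate(names):
        others = [c for c in range(len(names)) if c != j]
        A = np.column_stack([np.ones(n), X[:, others]])
        y = X[:, j]
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ beta
        sst = ((y - y.mean()) ** 2).sum()
        r2 = 1.0 - resid @ resid / sst if sst > 0 else 1.0
        vifs[name] = math.inf if 1.0 - r2 < 1e-12 else 1.0 / (1.0 - r2)
    return CollinearityReport(r, pd.Series(vifs, name="VIF"))


# -- sampling-effort arithmetic -------------------------------------------


def _check_nonneg(**kw):
    for name, v in kw.items():
        if v < 0:
            raise ValueError(f"{name} must be non-negative, got {v}")


def mistnet_night_effort(net_area: float, n_nets: float, hours: float) -> float:
    """Mist-net effort for one night: net area (m^2) x nets x hours."""
    _check_nonneg(net_area=net_area, n_nets=n_nets, hours=hours)
    return net_area * n_nets * hours


def mistnet_effort(per_night_effort: float, nights: float) -> float:
    """Accumulated mist-net effort (m^2 h) over a number of sampling nights."""
    _check_nonneg(per_night_effort=per_night_effort, nights=nights)
    return per_night_effort * nights


def aru_files(n_units: int, nights: int, files_per_night: int) -> int:
    """Number of audio files recorded by ``n_units`` recorders."""
    _check_nonneg(n_units=n_units, nights=nights, files_per_night=files_per_night)
    return int(n_units) * int(nights) * int(files_per_night)


def aru_effort(n_units: int, nights: int, files_per_night: int,
               file_seconds: float) -> float:
    """Acoustic effort in recorder-hours: files x file duration / 3600."""
    _check_nonneg(n_units=n_units, nights=nights,
                  files_per_night=files_per_night, file_seconds=file_seconds)
    if file_seconds > 60:
        raise ValueError("file_seconds cannot exceed 60 (one file per minute)")
    return aru_files(n_units, nights, files_per_night) * file_seconds / 3600.0


@dataclass
class EffortRecord:
    """A named sampling-effort computation; effort is the product of its factors."""

    method: str
    factors: dict
    effort: float
    unit: str

    @classmethod
    def mist_net(cls, per_night_effort: float, nights: float) -> "EffortRecord":
        return cls(
            method="mist_net",
            factors={"per_night_effort_m2h": per_night_effort, "nights": nights},
            effort=mistnet_effort(per_night_effort, nights),
            unit="m2.h",
        )

    @classmethod
    def aru(cls, n_units: int, nights: int, files_per_night: int,
            file_seconds: float) -> "EffortRecord":
        return cls(
            method="aru",
            factors={
                "n_units": n_units,
                "nights": nights,
                "files_per_night": files_per_night,
                "file_seconds": file_seconds,
            },
            effort=aru_effort(n_units, nights, files_per_night, file_seconds),
            unit="recorder.h",
        )

    def to_json(self) -> str:
        return json.dumps(
            {"method": self.method, "factors": self.factors,
             "effort": self.effort, "unit": self.unit}
        )
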