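"""Long-format municipal panel container.

A :class:`MunicipalPanel` wraps a tidy pandas DataFrame with one row per
(municipality, year): population, covariates, ESF coverage, Mais Medicos
doctor counts and death counts per outcome stratum (columns
``deaths_<stratum>``).  Race-stratified person-years are split by the
static ``race_mix`` column (fraction black/pardo).
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .effects import COVARIATES, RACE_STRATA

__all__ = ["MunicipalPanel"]

_CORE_COLUMNS = ("muni_id", "year", "population")


class MunicipalPanel:
    def __init__(
        self,
        data: pd.DataFrame,
        covariates: Iterable[str] = COVARIATES,
        truth: Mapping | None = None,
        validate: bool = True,
    ) -> None:
        self.data = data.sort_values(["muni_id", "year"], kind="stable").reset_index(
            drop=True
        )
        self.covariates = tuple(covariates)
        #: generator ground truth (true fixed effects, trend rates) when the
        #: panel is synthetic; empty for panels read from disk.
        self.truth: dict = dict(truth or {})
        if validate:
            self.validate()

    # -- structure ---------------------------------------------------------

    @property
    def years(self) -> np.ndarray:
        return np.sort(self.data["year"].unique())

    @property
    def muni_ids(self) -> np.ndarray:
        return self.data["muni_id"].unique()

    @property
    def n_municipalities(self) -> int:
        return self.data["muni_id"].nunique()

    @property
    def strata(self) -> tuple:
        return tuple(
            c[len("deaths_") :] for c in self.data.columns if c.startswith("deaths_")
        )

    def validate(self) -> None:
        df = self.data
        for col in _CORE_COLUMNS:
            if col not in df.columns:
                raise ValueError(f"panel is missing required column {col!r}")
        if df.duplicated(["muni_id", "year"]).any():
            raise ValueError("panel has duplicate (muni_id, year) rows")
        if (df["population"] <= 0).any():
            raise ValueError("populations must be strictly positive")
        spans = df.groupby("muni_id")["year"].agg(["min", "max", "size"])
        if ((spans["max"] - spans["min"] + 1) != spans["size"]).any():
            bad = spans.index[(spans["max"] - spans["min"] + 1) != spans["size"]]
            raise ValueError(f"years not contiguous for municipalities {list(bad)[:5]}")
        if "esf_coverage" in df.columns:
            cov = df["esf_coverage"].dropna()
            if ((cov < 0) | (cov > 1)).any():
                raise ValueError("esf_coverage must lie in [0, 1]")
        if "mmp_doctors" in df.columns:
            if (df["mmp_doctors"].dropna() < 0).any():
                raise ValueError("mmp_doctors must be non-negative")
        for stratum in self.strata:
            d = df[f"deaths_{stratum}"].dropna()
            if (d < 0).any():
                raise ValueError(f"negative deaths in stratum {stratum!r}")
            if (df.loc[d.index, "population"] < d).any():
                raise ValueError(f"deaths exceed population in stratum {stratum!r}")

    # -- accessors ---------------------------------------------------------

    def person_years(self, stratum: str) -> pd.Series:
        """Person-years at risk for a stratum (race strata split by race_mix)."""
        pop = self.data["population"].astype(float)
        if stratum in RACE_STRATA:
            if "race_mix" not in self.data.columns:
                raise ValueError("race-stratified person-years need a race_mix column")
            frac = self.data["race_mix"]
            return pop * (frac if stratum == "acsc_black" else 1.0 - frac)
        return pop

    def deaths(self, stratum: str) -> pd.Series:
        col = f"deaths_{stratum}"
        if col not in self.data.columns:
            raise KeyError(f"panel has no deaths for stratum {stratum!r}")
        return self.data[col]

    def baseline_covariate(self, name: str, year: int = 2010) -> pd.Series:
        """One value per municipality of a covariate at a baseline year."""
        rows = self.data[self.data["year"] == year]
        if rows.empty:
            raise ValueError(f"panel has no rows for baseline year {year}")
        if name not in rows.columns:
            raise KeyError(f"panel has no covariate {name!r}")
        return rows.set_index("muni_id")[name]

    def subset_years(self, start: int, end: int) -> "MunicipalPanel":
        mask = (self.data["year"] >= start) & (self.data["year"] <= end)
        return MunicipalPanel(
            self.data[mask], self.covariates, truth=self.truth, validate=False
        )

    def pivot(self, column: str, years: Iterable[int] | None = None) -> pd.DataFrame:
        """Wide municipality x year matrix of one column (rows ordered by muni_id)."""
        wide = self.data.pivot(index="muni_id", columns="year", values=column)
        if years is not None:
            wide = wide.reindex(columns=list(years))
        return wide.sort_index()

    # -- I/O ---------------------------------------------------------------

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def read_csv(cls, path, covariates: Iterable[str] = COVARIATES) -> "MunicipalPanel":
        df = pd.read_csv(path)
        present = [c for c in covariates if c in df.columns]
        return cls(df, covariates=present)

    def __repr__(self) -> str:  # pragma: no cover
        yrs = self.years
        return (
            f"<MunicipalPanel: {self.n_municipalities} municipalities, "
            f"years {yrs.min()}-{yrs.max()}, strata {list(self.strata)}>"
        )
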