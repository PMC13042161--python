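"""Tau load and tau presence from regional SUVR-like cohort tables.

Two complementary measures are derived from a participants x regions table of
tracer-uptake values:

* **tau load** - per-region MinMax normalization against a tau-negative
  reference group, so 0-1 spans the reference range and pathological values
  may exceed 1;
* **tau presence (TPP)** - the posterior probability of the higher-mean
  component of a per-region two-component Gaussian mixture fitted across the
  whole cohort, interpreted as the confidence that tau pathology has reached
  the region irrespective of its amount.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, spearmanr

GROUPS = ("reference", "positive")


class DegenerateReferenceError(ValueError):
    """Raised when a region's reference group has zero value range."""


@dataclass
class CohortTauTable:
    """Participants x regions tracer values with group labels."""

    values: np.ndarray
    participant_ids: list[str]
    group_labels: list[str]
    region_labels: list[str]

    def __post_init__(self) -> None:
        V = np.asarray(self.values, dtype=float)
        if V.ndim != 2:
            raise ValueError("values must be a participants x regions matrix")
        if not np.all(np.isfinite(V)) or np.any(V <= 0):
            raise ValueError("all values must be finite and > 0")
        self.values = V
        if len(self.participant_ids) != V.shape[0]:
            raise ValueError("participant_ids length mismatch")
        if len(self.group_labels) != V.shape[0]:
            raise ValueError("group_labels length mismatch")
        bad = set(self.group_labels) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        if len(self.region_labels) != V.shape[1]:
            raise ValueError("region_labels length mismatch")
        if len(set(self.region_labels)) != len(self.region_labels):
            raise ValueError("region labels must be unique")
        if "reference" not in self.group_labels:
            raise ValueError("at least one reference participant is required")

    @property
    def n_participants(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]

    def group_mask(self, group: str) -> np.ndarray:
        return np.array([g == group for g in self.group_labels])

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.region_labels)
        df.insert(0, "group", self.group_labels)
        df.insert(0, "participant_id", self.participant_ids)
        return df

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "CohortTauTable":
        df = pd.read_csv(path, sep="\t")
        regions = [c for c in df.columns if c not in ("participant_id", "group")]
        return cls(
            df[regions].to_numpy(float),
            [str(p) for p in df["participant_id"]],
            list(df["group"]),
            regions,
        )


@dataclass
class TauMeasures:
    """Per-participant tau load and presence plus the fitted mixture params."""

    load: np.ndarray
    tpp: np.ndarray
    gmm_params: pd.DataFrame
    region_labels: list[str]


def minmax_normalize_load(
    table: CohortTauTable, clip_negative: bool = True
) -> np.ndarray:
    """Reference-group MinMax normalization per region.

    ``load = (x - min_ref) / (max_ref - min_ref)``; the reference extremes map
    to 0 and 1, positive participants may exceed 1, and sub-reference values
    are clipped to 0.
    """
    ref = table.values[table.group_mask("reference")]
    if ref.shape[0] < 2:
        raise ValueError("load normalization requires >= 2 reference participants")
    lo = ref.min(axis=0)
    rng = ref.max(axis=0) - lo
    if np.any(rng <= 0):
        region = table.region_labels[int(np.argmax(rng <= 0))]
        raise DegenerateReferenceError(
            f"zero reference range in region {region!r}; cannot MinMax normalize"
        )
    load = (table.values - lo) / rng
    if clip_negative:
        load = np.clip(load, 0.0, None)
    return load


def _fit_two_gaussians(
    x: np.ndarray,
    max_iter: int = 500,
    tol: float = 1e-8,
    var_floor_frac: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic EM for a 1-D two-component Gaussian mixture.

    Components are seeded at the 25th/75th percentiles, variances are floored
    at ``var_floor_frac`` times the sample variance, and components are
    relabelled by ascending mean after convergence.  Returns
    ``(weights, means, sds)``.
    """
    x = np.asarray(x, float)
    total_var = x.var()
    if total_var == 0.0:
        raise ValueError("zero-variance sample; mixture undefined")
    floor = var_floor_frac * total_var
    # k-means-style initialization from quantile seeds: hard-assign each point
    # to the nearer of the 25th/75th-percentile seeds and moment-match the
    # resulting partition (starts EM in the mean-split basin rather than the
    # spurious narrow-component-on-the-mode basin)
    seeds = np.percentile(x, [25.0, 75.0])
    if seeds[0] == seeds[1]:
        seeds = seeds + np.array([-1.0, 1.0]) * np.sqrt(total_var) / 2
    assign = np.abs(x[:, None] - seeds[None, :]).argmin(axis=1)
    w = np.empty(2)
    mu = np.empty(2)
    var = np.empty(2)
    for k in range(2):
        members = x[assign == k]
        if members.size == 0:
            members = np.array([seeds[k]])
        w[k] = max(members.size, 1) / x.size
        mu[k] = members.mean()
        var[k] = max(members.var(), floor, 1e-12)
    w = w / w.sum()

    prev_ll = -np.inf
    for _ in range(max_iter):
        # E-step in log space for numerical stability
        log_resp = (
            np.log(w)[:, None]
            - 0.5 * np.log(2 * np.pi * var)[:, None]
            - 0.5 * (x[None, :] - mu[:, None]) ** 2 / var[:, None]
        )
        log_norm = np.logaddexp(log_resp[0], log_resp[1])
        ll = log_norm.sum()
        resp = np.exp(log_resp - log_norm)
        # M-step
        nk = resp.sum(axis=1)
        nk = np.maximum(nk, 1e-12)
        w = nk / x.size
        mu = (resp @ x) / nk
        var = (resp @ x**2) / nk - mu**2
        var = np.maximum(var, floor)
        if abs(ll - prev_ll) < tol:
            break
        prev_ll = ll

    order = np.argsort(mu)
    return w[order], mu[order], np.sqrt(var[order])


def posterior_high_component(
    x: np.ndarray, w: np.ndarray, mu: np.ndarray, sd: np.ndarray
) -> np.ndarray:
    """Posterior probability of the higher-mean component at values ``x``."""
    log_p = np.stack(
        [np.log(w[k]) + norm.logpdf(x, mu[k], sd[k]) for k in range(2)]
    )
    return np.exp(log_p[1] - np.logaddexp(log_p[0], log_p[1]))


def fit_tpp(
    table: CohortTauTable,
    min_participants: int = 10,
    separation_sd: float = 0.5,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Fit a per-region two-component mixture and return the TPP matrix.

    A region whose fitted component means differ by less than
    ``separation_sd`` pooled standard deviations is flagged as near-unimodal;
    its TPP is still computed from the relabelled fit.
    """
    if table.n_participants < min_participants:
        raise ValueError(
            f"TPP requires >= {min_participants} participants, got {table.n_participants}"
        )
    tpp = np.empty_like(table.values)
    rows = []
    for j, region in enumerate(table.region_labels):
        x = table.values[:, j]
        w, mu, sd = _fit_two_gaussians(x)
        tpp[:, j] = posterior_high_component(x, w, mu, sd)
        pooled_sd = float(np.sqrt(w @ sd**2))
        flagged = (mu[1] - mu[0]) < separation_sd * pooled_sd
        rows.append(
            dict(region=region, w_low=w[0], mu_low=mu[0], sd_low=sd[0],
                 w_high=w[1], mu_high=mu[1], sd_high=sd[1], flagged=flagged)
        )
    return tpp, pd.DataFrame(rows)


def quantify_cohort(table: CohortTauTable, **tpp_kwargs) -> TauMeasures:
    """Convenience: compute both tau load and TPP for a cohort table."""
    load = minmax_normalize_load(table)
    tpp, params = fit_tpp(table, **tpp_kwargs)
    return TauMeasures(load, tpp, params, list(table.region_labels))


def group_average_map(
    measures: TauMeasures | np.ndarray,
    subset: np.ndarray | Sequence[int],
    which: str = "load",
) -> np.ndarray:
    """Arithmetic mean per region over the selected participants."""
    if isinstance(measures, TauMeasures):
        matrix = measures.load if which == "load" else measures.tpp
    else:
        matrix = np.asarray(measures, float)
    subset = np.asarray(subset)
    sub = matrix[subset]
    if sub.size == 0:
        raise ValueError("empty participant subset")
    return sub.mean(axis=0)


def braak_summary(
    regional_map: np.ndarray,
    region_labels: Sequence[str],
    braak_assignment: Mapping[str, str],
) -> tuple[pd.DataFrame, float]:
    """Per-Braak-stage mean, SEM and region count, plus a monotonic-trend
    diagnostic (Spearman correlation of stage index vs stage mean).

    SEM is the sample standard deviation over member regions divided by
    sqrt(n); a single-region stage reports SEM 0 by convention, and an empty
    stage reports missing values.
    """
    regional_map = np.asarray(regional_map, float)
    stages = ("I", "II", "III", "IV", "V", "VI")
    rows = []
    for stage in stages:
        members = [
            i for i, lbl in enumerate(region_labels)
            if braak_assignment.get(lbl, "unassigned") == stage
        ]
        vals = regional_map[members]
        if len(members) == 0:
            rows.append(dict(stage=stage, mean=np.nan, sem=np.nan, n=0))
        elif len(members) == 1:
            rows.append(dict(stage=stage, mean=float(vals[0]), sem=0.0, n=1))
        else:
            rows.append(dict(
                stage=stage,
                mean=float(vals.mean()),
                sem=float(vals.std(ddof=1) / np.sqrt(len(members))),
                n=len(members),
            ))
    df = pd.DataFrame(rows)
    present = df.dropna(subset=["mean"])
    if len(present) >= 2 and present["mean"].nunique() > 1:
        rho = float(spearmanr(np.arange(len(present)), present["mean"]).statistic)
    else:
        rho = np.nan
    return df, rho
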