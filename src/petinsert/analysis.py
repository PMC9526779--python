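"""Image-quality quantification: VOI measurement, recovery coefficients,
and experimental-vs-simulated agreement.

A spherical VOI matched to each sphere's internal volume yields AC_mean
(fraction-weighted mean activity concentration) and AC_max (maximum voxel).
Recovery coefficients divide these by the theoretical concentration known
from phantom preparation:

    RC_mean/max = AC_mean/max / AC_theoretical

Per-replicate RCs are averaged (with SD) per (sphere, SBR, algorithm), and
two series are compared with the full battery: Mann-Whitney U on the RC
distributions, Spearman correlation of the paired values, D'Agostino-
Pearson normality of the paired differences, and Bland-Altman limits of
agreement — overall and per reconstruction algorithm.

The published reference RC tables (two algorithms x six spheres x four
SBRs, experimental and simulated arms) ship with the package as a fixture
for the agreement battery; the BPL rows are consumed as data only — that
regularized algorithm is not implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import VolumeImage
from .insertion import VoiSpec
from .spheres import generate_sphere_mask
from .stats import bland_altman, dagostino_pearson, mann_whitney_u, spearman_rho

__all__ = [
    "VoiMeasurement",
    "RCRecord",
    "AgreementStats",
    "voi_measure",
    "recovery_coefficient",
    "build_rc_table",
    "compare_series",
    "load_reference_rc_tables",
    "plot_agreement",
]


@dataclass(frozen=True)
class VoiMeasurement:
    """Mean and maximum activity concentration within one VOI (kBq/mL)."""

    ac_mean: float
    ac_max: float


@dataclass(frozen=True)
class RCRecord:
    """Recovery coefficients of one sphere under one condition."""

    sphere_mm: float
    sbr: float
    algorithm: str
    ac_theoretical: float
    rc_mean: float
    rc_max: float


@dataclass(frozen=True)
class AgreementStats:
    """One row of the agreement battery between two RC series."""

    label: str
    n: int
    mw_u: float
    mw_p: float
    rho: float
    rho_p: float
    k2: float
    k2_p: float
    ba_mean_pct: float
    ba_halfwidth_pct: float


def voi_measure(
    img: VolumeImage, voi: VoiSpec, factor: int = 8
) -> VoiMeasurement:
    """Measure AC_mean (fraction-weighted) and AC_max (plain voxel maximum
    over voxels with any VOI coverage) inside a spherical VOI.

    The VOI mask uses the same fractional sub-voxel machinery as the sphere
    modeling, so identical VOI definitions can be reused across series.
    """
    mask = generate_sphere_mask(img.grid, voi.as_sphere(), factor)
    w = mask.values
    total = w.sum()
    if total == 0:
        raise ValueError(f"VOI {voi} covers no voxels")
    ac_mean = float((w * img.values).sum() / total)
    ac_max = float(img.values[w > 0].max())
    return VoiMeasurement(ac_mean=ac_mean, ac_max=ac_max)


def recovery_coefficient(
    m: VoiMeasurement, ac_theoretical: float
) -> tuple[float, float]:
    """(RC_mean, RC_max) = measured / theoretical concentration."""
    if ac_theoretical <= 0:
        raise ValueError(f"ac_theoretical must be > 0, got {ac_theoretical}")
    return m.ac_mean / ac_theoretical, m.ac_max / ac_theoretical


def build_rc_table(
    measurements: pd.DataFrame, n_replicates: int = 3
) -> pd.DataFrame:
    """Average per-replicate recovery coefficients.

    ``measurements`` needs columns sphere_mm, sbr, algorithm, replicate,
    ac_mean, ac_max, ac_theoretical. RCs are computed per replicate first,
    then averaged and SD-ed (ddof=1) per (sphere_mm, sbr, algorithm).
    Raises if any group is missing a replicate.
    """
    required = {"sphere_mm", "sbr", "algorithm", "replicate", "ac_mean",
                "ac_max", "ac_theoretical"}
    missing = required - set(measurements.columns)
    if missing:
        raise ValueError(f"measurements missing columns {sorted(missing)}")
    df = measurements.copy()
    if (df["ac_theoretical"] <= 0).any():
        raise ValueError("ac_theoretical must be > 0")
    df["rc_mean"] = df["ac_mean"] / df["ac_theoretical"]
    df["rc_max"] = df["ac_max"] / df["ac_theoretical"]

    keys = ["sphere_mm", "sbr", "algorithm"]
    counts = df.groupby(keys)["replicate"].nunique()
    short = counts[counts != n_replicates]
    if not short.empty:
        raise ValueError(
            f"expected {n_replicates} replicates per condition; "
            f"offenders: {short.to_dict()}"
        )
    out = (
        df.groupby(keys)
        .agg(
            rc_mean_avg=("rc_mean", "mean"),
            rc_mean_sd=("rc_mean", lambda s: s.std(ddof=1)),
            rc_max_avg=("rc_max", "mean"),
            rc_max_sd=("rc_max", lambda s: s.std(ddof=1)),
        )
        .reset_index()
    )
    return out


_KEYS = ["algorithm", "sphere_mm", "sbr"]


def _round_keys(df: pd.DataFrame) -> pd.DataFrame:
    # SBR is a measured ratio; round the join key so that e.g. 3.93 pairs
    # with 21.38/5.44 = 3.9301... between independently produced tables.
    df = df.copy()
    df["sbr"] = df["sbr"].round(2)
    return df


def _paired(rc_exp: pd.DataFrame, rc_sim: pd.DataFrame) -> pd.DataFrame:
    e = _round_keys(rc_exp).set_index(_KEYS).sort_index()
    s = _round_keys(rc_sim).set_index(_KEYS).sort_index()
    only_e = e.index.difference(s.index)
    only_s = s.index.difference(e.index)
    if len(only_e) or len(only_s):
        raise ValueError(
            "series keys do not match; "
            f"experimental-only={list(only_e)}, simulated-only={list(only_s)}"
        )
    return e.join(s, lsuffix="_exp", rsuffix="_sim").reset_index()


def _agreement_row(
    label: str, exp: np.ndarray, sim: np.ndarray, convention: str
) -> AgreementStats:
    mw_u, mw_p = mann_whitney_u(exp, sim)
    rho, rho_p = spearman_rho(exp, sim)
    ba = bland_altman(exp, sim, convention=convention)
    if len(exp) >= 20 and np.ptp(ba.differences_pct) > 0:
        k2, k2_p = dagostino_pearson(ba.differences_pct)
    else:  # too few pairs (or all-equal differences): no normality verdict
        k2, k2_p = float("nan"), float("nan")
    return AgreementStats(
        label=label, n=len(exp), mw_u=mw_u, mw_p=mw_p, rho=rho, rho_p=rho_p,
        k2=k2, k2_p=k2_p,
        ba_mean_pct=ba.mean_pct, ba_halfwidth_pct=ba.halfwidth_pct,
    )


def compare_series(
    rc_exp: pd.DataFrame,
    rc_sim: pd.DataFrame,
    convention: str = "percent_of_reference",
) -> pd.DataFrame:
    """Full agreement battery between replicate-averaged RC tables.

    Both tables need columns algorithm, sphere_mm, sbr, rc_mean_avg,
    rc_max_avg with matching keys. Returns one row per (metric x subset):
    RC_mean and RC_max, each overall and restricted to each algorithm
    present (six rows for a two-algorithm design). The Bland-Altman percent
    convention used is recorded in the ``convention`` column.
    """
    paired = _paired(rc_exp, rc_sim)
    rows: list[AgreementStats] = []
    algorithms = list(dict.fromkeys(paired["algorithm"]))
    for metric in ("rc_mean", "rc_max"):
        e_all = paired[f"{metric}_avg_exp"].to_numpy()
        s_all = paired[f"{metric}_avg_sim"].to_numpy()
        rows.append(_agreement_row(metric.upper(), e_all, s_all, convention))
        for alg in algorithms:
            sel = paired["algorithm"] == alg
            rows.append(
                _agreement_row(
                    f"{alg} {metric.upper()}",
                    paired.loc[sel, f"{metric}_avg_exp"].to_numpy(),
                    paired.loc[sel, f"{metric}_avg_sim"].to_numpy(),
                    convention,
                )
            )
    out = pd.DataFrame([r.__dict__ for r in rows])
    out["convention"] = convention
    return out


def load_reference_rc_tables() -> tuple[pd.DataFrame, pd.DataFrame]:
    """The packaged published RC tables as (experimental, simulated)
    replicate-averaged tables suitable for :func:`compare_series`."""
    with resources.files("petinsert.data").joinpath("rc_tables.csv").open() as f:
        df = pd.read_csv(f)
    out = {}
    for arm in ("experimental", "simulated"):
        sub = df[df["arm"] == arm]
        wide = sub.pivot_table(
            index=_KEYS, columns="metric", values=["rc_avg", "rc_sd"]
        )
        wide.columns = [f"rc_{m}_{'avg' if v == 'rc_avg' else 'sd'}"
                        for v, m in wide.columns]
        out[arm] = wide.reset_index()
    return out["experimental"], out["simulated"]


def plot_agreement(
    rc_exp: pd.DataFrame,
    rc_sim: pd.DataFrame,
    out_dir: str | Path,
    convention: str = "percent_of_reference",
) -> list[Path]:
    """Correlation + Bland-Altman figure per metric; returns written paths."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paired = _paired(rc_exp, rc_sim)
    paths = []
    for metric in ("rc_mean", "rc_max"):
        e = paired[f"{metric}_avg_exp"].to_numpy()
        s = paired[f"{metric}_avg_sim"].to_numpy()
        ba = bland_altman(e, s, convention=convention)
        fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
        ax1.scatter(e, s, s=18)
        lim = [0, max(e.max(), s.max()) * 1.05]
        ax1.plot(lim, lim, "k--", lw=0.8)
        ax1.set_xlabel(f"experimental {metric}")
        ax1.set_ylabel(f"simulated {metric}")
        avg = (e + s) / 2
        ax2.scatter(avg, ba.differences_pct, s=18)
        for yv, style in ((ba.mean_pct, "-"),
                          (ba.mean_pct + ba.halfwidth_pct, "--"),
                          (ba.mean_pct - ba.halfwidth_pct, "--")):
            ax2.axhline(yv, color="k", ls=style, lw=0.8)
        ax2.set_xlabel(f"mean {metric}")
        ax2.set_ylabel("difference (%)")
        fig.tight_layout()
        path = out_dir / f"agreement_{metric}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths.append(path)
    return paths
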