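"""End-to-end screen orchestration.

Ties the stages together: plate scheduling, image quantification,
normalization, curve fitting, potency metrics, ranking, and report
files, with a run manifest that accounts for every record and logs
every exclusion (flagged embryos, dropped top concentrations, design-
rule warnings). Warnings never abort a run — screening campaigns favour
robustness, and all rule violations are recorded instead.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import doseresponse as dr
from . import imaging

__all__ = ["AssayConfig", "schedule_wells", "run_screen", "report_tables"]


@dataclass
class AssayConfig:
    """All tunable constants of a screening run, in one serializable place.

    Imaging: ``ball_radius`` (px), ``threshold`` (grey levels, 8-bit
    scale), ``dilation_radius`` (px), ``min_spot_area`` (px). Fitting:
    ``fix_min`` (normalized control level), ``bmd_target`` (fold
    induction defining the benchmark dose), ``decline_margin`` (relative
    drop that triggers top-concentration exclusion). Design:
    ``min_images_per_conc`` (minimum usable embryos per concentration
    before a warning). ``qsar`` holds optional (slope, intercept) of
    the baseline-toxicity model.
    """

    ball_radius: int = 50
    threshold: float = 20.0
    dilation_radius: int = 2
    min_spot_area: int = 10
    fix_min: float = 1.0
    bmd_target: float = 1.2
    decline_margin: float = 0.10
    min_images_per_conc: int = 10
    qsar: tuple[float, float] | None = None
    seed: int = 0

    def imaging_params(self) -> imaging.ImagingParams:
        return imaging.ImagingParams(
            ball_radius=self.ball_radius,
            threshold=self.threshold,
            dilation_radius=self.dilation_radius,
            min_spot_area=self.min_spot_area,
        )

    def to_yaml(self, path) -> None:
        data = asdict(self)
        if data["qsar"] is not None:
            data["qsar"] = list(data["qsar"])
        Path(path).write_text(yaml.safe_dump(data))

    @classmethod
    def from_yaml(cls, path) -> "AssayConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if data.get("qsar") is not None:
            data["qsar"] = tuple(data["qsar"])
        return cls(**data)


def schedule_wells(layout: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Interleave treatment groups across the acquisition sequence.

    Imaging a plate takes hours; acquiring all of one treatment group
    first would confound treatment with time. The schedule deals wells
    round-robin — each round visits every (compound, concentration,
    replicate) group once in a freshly shuffled order — so every group's
    acquisition ranks are spread uniformly over the whole run.
    Deterministic for a fixed seed.
    """
    if "well" not in layout.columns:
        raise ValueError("layout must have a 'well' column")
    if layout["well"].duplicated().any():
        dupes = layout.loc[layout["well"].duplicated(), "well"].tolist()
        raise ValueError(f"duplicate wells in layout: {dupes}")
    rng = np.random.default_rng(seed)
    group_cols = [c for c in ("compound", "concentration_uM", "replicate")
                  if c in layout.columns]
    queues = {
        key: list(rng.permutation(grp.index.to_numpy()))
        for key, grp in layout.groupby(group_cols, sort=True)
    }
    order: list[int] = []
    keys = sorted(queues, key=str)
    while any(queues[k] for k in keys):
        round_keys = [k for k in keys if queues[k]]
        for k in rng.permutation(len(round_keys)):
            order.append(queues[round_keys[k]].pop())
    out = layout.loc[order].reset_index(drop=True)
    out["acquisition_order"] = np.arange(len(out))
    return out


def _file_checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_screen(
    measurements: pd.DataFrame | None = None,
    layout: pd.DataFrame | None = None,
    mortality: pd.DataFrame | None = None,
    compounds: pd.DataFrame | None = None,
    config: AssayConfig | None = None,
    image_root: str | Path | None = None,
) -> tuple[list[dr.PotencyReport], dict]:
    """Run the full analysis: images (or measurements) to potency report.

    Either ``layout`` (a plate table pointing at image files, quantified
    here) or ``measurements`` (a per-embryo pixel-sum table) must be
    given. ``mortality`` supplies per-concentration death counts for the
    LC50 stage and ``compounds`` per-compound metadata (cas, log_d).
    Returns the ranked per-compound reports plus a run manifest
    recording the config snapshot, record accounting and every
    exclusion.
    """
    config = config or AssayConfig()
    manifest: dict = {
        "software_version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "counts": {},
        "exclusions": [],
        "warnings": [],
    }

    if measurements is None:
        if layout is None:
            raise ValueError("provide either measurements or layout")
        measurements = imaging.quantify_layout(
            layout, params=config.imaging_params(), image_root=image_root
        )
    manifest["counts"]["n_images"] = int(len(measurements))
    flagged = measurements["flagged"].astype(bool) if "flagged" in measurements else (
        pd.Series(False, index=measurements.index)
    )
    manifest["counts"]["n_flagged"] = int(flagged.sum())
    manifest["counts"]["n_measured"] = int((~flagged).sum())
    for _, row in measurements[flagged].iterrows():
        manifest["exclusions"].append(
            {"record": str(row.get("embryo_id", "?")), "reason": "no gland detected"}
        )

    normalized = dr.normalize_to_control(measurements)
    low = normalized[normalized["low_n"]]
    for _, row in low.iterrows():
        manifest["warnings"].append(
            f"{row['compound']} rep {row['replicate']} at {row['concentration_uM']:g} uM: "
            f"only {row['n_embryos']} usable embryos (< {config.min_images_per_conc})"
        )
    normalized, excluded_tops = dr.exclude_declining_top(
        normalized, margin=config.decline_margin
    )
    for comp, conc in excluded_tops.items():
        manifest["exclusions"].append(
            {
                "record": f"{comp} @ {conc:g} uM",
                "reason": "declining response at top concentration",
            }
        )

    meta = {}
    if compounds is not None:
        meta = compounds.set_index("compound").to_dict("index")
    mort_by_comp = {}
    if mortality is not None:
        mort_by_comp = dict(tuple(mortality.groupby("compound")))

    reports: list[dr.PotencyReport] = []
    for compound, grp in normalized.groupby("compound"):
        rep = dr.PotencyReport(compound=compound)
        info = meta.get(compound, {})
        rep.cas = info.get("cas")
        rep.log_d = float(info.get("log_d", float("nan")))
        rep.excluded_top_concentration = excluded_tops.get(compound)
        try:
            hill = dr.fit_hill(grp, fix_min=config.fix_min)
        except ValueError as err:
            rep.warnings.append(f"induction fit failed: {err}")
            hill = None
        if hill is not None:
            rep.hill = hill
            rep.no_induction = hill.no_induction
            if not hill.converged:
                rep.warnings.append("induction fit did not converge")
            rep.ec50 = hill.EC50
            rep.ec50_se = hill.EC50_SE
            rep.slope = hill.slope
            rep.max_fold = hill.Max
            if not hill.no_induction and hill.converged:
                try:
                    rep.bmd20 = dr.compute_bmd(hill, config.bmd_target)
                except ValueError as err:
                    rep.warnings.append(f"benchmark dose undefined: {err}")

        if compound in mort_by_comp:
            fit = dr.fit_mortality(mort_by_comp[compound])
            rep.lc50 = fit.lc50
            rep.lc50_flag = "" if fit.method == "ml" else fit.method
        if config.qsar is not None and np.isfinite(rep.log_d):
            rep.baseline_lc50 = dr.baseline_toxicity(rep.log_d, config.qsar)
            if np.isfinite(rep.lc50) and not rep.lc50_flag == "censored":
                rep.toxic_ratio, rep.baseline_like = dr.toxic_ratio(
                    rep.baseline_lc50, rep.lc50
                )
        if np.isfinite(rep.ec50):
            if np.isfinite(rep.lc50) and rep.lc50_flag != "censored":
                rep.tdi = dr.compute_tdi(rep.lc50, rep.ec50)
            elif np.isfinite(rep.baseline_lc50):
                # no observed mortality up to the tested range: fall back
                # to the predicted baseline LC50 for the disruption index
                rep.tdi = dr.compute_tdi(rep.baseline_lc50, rep.ec50)
                rep.warnings.append("TDI from predicted baseline LC50 (censored LC50)")
        reports.append(rep)

    reports = dr.rank_compounds(reports, key="EC50")
    manifest["counts"]["n_compounds"] = len(reports)
    manifest["excluded_top_concentrations"] = excluded_tops
    return reports, manifest


def _report_row(rep: dr.PotencyReport) -> dict:
    return {
        "compound": rep.compound,
        "cas": rep.cas,
        "log_d": rep.log_d,
        "lc50": rep.lc50,
        "lc50_flag": rep.lc50_flag,
        "ec50": rep.ec50,
        "ec50_se": rep.ec50_se,
        "slope": rep.slope,
        "max_fold": rep.max_fold,
        "bmd20": rep.bmd20,
        "tdi": rep.tdi_display,
        "toxic_ratio": rep.toxic_ratio,
        "no_induction": rep.no_induction,
    }


def _curve_band(hill: dr.HillParameters, grid: np.ndarray, level: float = 0.95):
    """Fitted curve with a delta-method confidence band."""
    from scipy import stats

    y = hill(grid)
    if hill.cov is None:
        return y, y, y
    theta = np.array([hill.Max, np.log10(hill.EC50), hill.slope])

    def f(t, x):
        return dr.hill_curve(x, hill.Min, t[0], 10.0 ** t[1], t[2])

    grads = np.empty((len(grid), 3))
    eps = 1e-6
    for j in range(3):
        dt = np.zeros(3)
        dt[j] = eps * max(abs(theta[j]), 1.0)
        grads[:, j] = (f(theta + dt, grid) - f(theta - dt, grid)) / (2 * dt[j])
    var = np.einsum("ij,jk,ik->i", grads, hill.cov, grads)
    df = max(hill.n_points - 3, 1)
    tq = stats.t.ppf(0.5 + level / 2.0, df)
    half = tq * np.sqrt(np.clip(var, 0, None))
    return y, y - half, y + half


def report_tables(
    reports: list[dr.PotencyReport],
    out_dir: str | Path,
    manifest: dict | None = None,
    n_grid: int = 100,
) -> dict[str, Path]:
    """Write the summary table and per-compound curve files.

    ``summary.csv`` mirrors a potency-report table (one compound per
    row; undefined metrics are empty cells, never zeros). Each compound
    with a successful induction fit also gets
    ``curves/<compound>.csv`` holding the fitted curve on a log-spaced
    concentration grid with a 95% confidence band from the parameter
    covariance.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    summary = pd.DataFrame([_report_row(r) for r in reports])
    summary_path = out_dir / "summary.csv"
    summary.to_csv(summary_path, index=False)
    files["summary"] = summary_path

    curve_dir = out_dir / "curves"
    for rep in reports:
        hill = rep.hill
        if hill is None or not np.isfinite(hill.EC50):
            continue
        curve_dir.mkdir(exist_ok=True)
        grid = np.geomspace(hill.EC50 / 100.0, hill.EC50 * 100.0, n_grid)
        y, lo, hi = _curve_band(hill, grid)
        slug = rep.compound.replace(" ", "_").replace("/", "-")
        path = curve_dir / f"{slug}.csv"
        pd.DataFrame(
            {
                "concentration_uM": grid,
                "fitted_fold": y,
                "ci_lower": lo,
                "ci_upper": hi,
            }
        ).to_csv(path, index=False)
        files[f"curve:{rep.compound}"] = path

    if manifest is not None:
        manifest_path = out_dir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
        files["manifest"] = manifest_path
    return files
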