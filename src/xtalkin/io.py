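"""CSV readers/writers, run configuration and the pipeline driver.

All tabular interchange uses plain CSV with explicit headers:

* ``induction_times.csv`` — vial_id, supersaturation, time_min, nucleated
  (0/1; censored vials carry the censor time and nucleated = 0)
* ``counts.csv`` — vial_id, supersaturation, time_min, count
* ``psd.csv`` (long) — vial_id, supersaturation, time_min, bin_index
  (0–98), count; bin edges follow the 3–300 um / 99-bin convention
* ``clear_points.csv`` — concentration_mg_per_g, heating_rate_C_per_min,
  clear_point_C, replicate
* ``solubility.csv`` — temperature_C, solubility_mg_per_g

Schema violations are collected and reported together with row numbers.
``run_pipeline`` chains the stages in workflow order (solubility →
induction → seeded rates → mechanism → MSMPR guidance); a stage failure
is recorded and its dependents skipped with an explanation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from xtalkin import core, induction, mechanism, msmpr, secondary
from xtalkin.errors import ValidationError, XtalkinError


@dataclass
class RunConfig:
    """Study-level configuration with the experimental defaults.

    3 mL vials held for 4 h, counts calibrated at ``calibration_factor``
    (particles/mL per count/image), slope fits restricted to the 10–160
    count window, glycine solubility reference 249.52 mg/g at 25 degC.
    """

    volume_mL: float = 3.0
    censor_time_min: float = 240.0
    calibration_factor: float = secondary.DEFAULT_CALIBRATION
    window_low: float = secondary.DEFAULT_WINDOW_LOW
    window_high: float = secondary.DEFAULT_WINDOW_HIGH
    solubility_ref_mg_per_g: float = core.DEFAULT_SOLUBILITY_MG_PER_G
    seed: int = 0
    output_dir: str = "results"
    msmpr_phi: float | None = None
    msmpr_d43_m: float | None = None
    msmpr_tau_s: float | None = None

    def __post_init__(self) -> None:
        failures = []
        for name in (
            "volume_mL",
            "censor_time_min",
            "calibration_factor",
            "solubility_ref_mg_per_g",
        ):
            if getattr(self, name) <= 0:
                failures.append(f"{name} must be positive")
        if self.window_low >= self.window_high:
            failures.append("window_low must be below window_high")
        if failures:
            raise ValidationError(failures)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _require_columns(df: pd.DataFrame, required: list[str], name: str) -> list[str]:
    return [
        f"{name}: missing column '{c}'" for c in required if c not in df.columns
    ]


def read_induction_times(
    path: str | Path, config: RunConfig | None = None
) -> dict[float, induction.InductionDataset]:
    """Read ``induction_times.csv`` into per-supersaturation datasets."""
    config = config or RunConfig()
    df = pd.read_csv(path)
    failures = _require_columns(
        df, ["vial_id", "supersaturation", "time_min", "nucleated"], "induction"
    )
    if failures:
        raise ValidationError(failures)
    for i, row in df.iterrows():
        if row["time_min"] <= 0:
            failures.append(f"induction row {i}: non-positive time")
        if row["nucleated"] not in (0, 1):
            failures.append(f"induction row {i}: nucleated must be 0 or 1")
    if failures:
        raise ValidationError(failures)
    out: dict[float, induction.InductionDataset] = {}
    for S, grp in df.groupby("supersaturation"):
        observed = grp.loc[grp["nucleated"] == 1, "time_min"].to_numpy(float)
        out[float(S)] = induction.InductionDataset(
            supersaturation=float(S),
            times=observed,
            n_censored=int((grp["nucleated"] == 0).sum()),
            volume_mL=config.volume_mL,
            censor_time=config.censor_time_min,
            vial_ids=grp["vial_id"].astype(str).tolist(),
        )
    return out


def write_induction_times(
    datasets: dict[float, induction.InductionDataset], path: str | Path
) -> None:
    rows = []
    for S, ds in sorted(datasets.items()):
        for i, t in enumerate(ds.times):
            rows.append((f"S{S:.4f}-v{i}", S, float(t), 1))
        for j in range(ds.n_censored):
            rows.append((f"S{S:.4f}-c{j}", S, ds.censor_time, 0))
    pd.DataFrame(
        rows, columns=["vial_id", "supersaturation", "time_min", "nucleated"]
    ).to_csv(path, index=False)


def read_counts(
    path: str | Path, config: RunConfig | None = None
) -> dict[float, list[secondary.CountSeries]]:
    """Read ``counts.csv`` into per-supersaturation count traces."""
    config = config or RunConfig()
    df = pd.read_csv(path)
    failures = _require_columns(
        df, ["vial_id", "supersaturation", "time_min", "count"], "counts"
    )
    if failures:
        raise ValidationError(failures)
    neg = df.index[df["count"] < 0].tolist()
    failures.extend(f"counts row {i}: negative count" for i in neg)
    for vid, grp in df.groupby("vial_id"):
        t = grp["time_min"].to_numpy(float)
        if np.any(np.diff(t) <= 0):
            failures.append(f"counts vial {vid}: non-monotone time")
    if failures:
        raise ValidationError(failures)
    out: dict[float, list[secondary.CountSeries]] = {}
    for (S, vid), grp in df.groupby(["supersaturation", "vial_id"]):
        out.setdefault(float(S), []).append(
            secondary.CountSeries(
                vial_id=str(vid),
                supersaturation=float(S),
                times=grp["time_min"].to_numpy(float),
                counts=grp["count"].to_numpy(float),
                calibration_factor=config.calibration_factor,
            )
        )
    return out


def write_counts(
    series: dict[float, list[secondary.CountSeries]], path: str | Path
) -> None:
    rows = []
    for S, lst in sorted(series.items()):
        for cs in lst:
            for t, c in zip(cs.times, cs.counts):
                rows.append((cs.vial_id, S, float(t), float(c)))
    pd.DataFrame(
        rows, columns=["vial_id", "supersaturation", "time_min", "count"]
    ).to_csv(path, index=False)


def read_psd(path: str | Path) -> dict[float, list[secondary.PSDSeries]]:
    """Read long-format ``psd.csv`` into per-supersaturation PSD series."""
    df = pd.read_csv(path)
    failures = _require_columns(
        df,
        ["vial_id", "supersaturation", "time_min", "bin_index", "count"],
        "psd",
    )
    if failures:
        raise ValidationError(failures)
    neg = df.index[df["count"] < 0].tolist()
    failures.extend(f"psd row {i}: negative count" for i in neg)
    for (vid, t), grp in df.groupby(["vial_id", "time_min"]):
        if len(grp) != secondary.PSD_N_BINS or set(
            grp["bin_index"].astype(int)
        ) != set(range(secondary.PSD_N_BINS)):
            failures.append(
                f"psd vial {vid} frame t={t}: expected "
                f"{secondary.PSD_N_BINS} bins (0..98)"
            )
    if failures:
        raise ValidationError(failures)
    out: dict[float, list[secondary.PSDSeries]] = {}
    for (S, vid), grp in df.groupby(["supersaturation", "vial_id"]):
        pivot = grp.pivot(index="time_min", columns="bin_index", values="count")
        pivot = pivot.sort_index()
        out.setdefault(float(S), []).append(
            secondary.PSDSeries(
                vial_id=str(vid),
                supersaturation=float(S),
                times=pivot.index.to_numpy(float),
                histograms=pivot.to_numpy(float),
            )
        )
    return out


def write_psd(
    series: dict[float, list[secondary.PSDSeries]], path: str | Path
) -> None:
    frames = []
    for S, lst in sorted(series.items()):
        for ps in lst:
            n_t = ps.times.size
            frames.append(
                pd.DataFrame(
                    {
                        "vial_id": np.repeat(ps.vial_id, n_t * secondary.PSD_N_BINS),
                        "supersaturation": S,
                        "time_min": np.repeat(ps.times, secondary.PSD_N_BINS),
                        "bin_index": np.tile(
                            np.arange(secondary.PSD_N_BINS), n_t
                        ),
                        "count": ps.histograms.ravel(),
                    }
                )
            )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_clear_points(path: str | Path) -> list[core.ClearPointTable]:
    df = pd.read_csv(path)
    failures = _require_columns(
        df,
        [
            "concentration_mg_per_g",
            "heating_rate_C_per_min",
            "clear_point_C",
            "replicate",
        ],
        "clear_points",
    )
    if failures:
        raise ValidationError(failures)
    tables = []
    for conc, grp in df.groupby("concentration_mg_per_g"):
        tables.append(
            core.ClearPointTable(
                concentration=float(conc),
                rows=[
                    (
                        float(r["heating_rate_C_per_min"]),
                        float(r["clear_point_C"]),
                        int(r["replicate"]),
                    )
                    for _, r in grp.iterrows()
                ],
            )
        )
    return tables


def read_solubility(path: str | Path) -> list[tuple[float, float]]:
    df = pd.read_csv(path)
    failures = _require_columns(
        df, ["temperature_C", "solubility_mg_per_g"], "solubility"
    )
    if failures:
        raise ValidationError(failures)
    return [
        (float(r["temperature_C"]), float(r["solubility_mg_per_g"]))
        for _, r in df.iterrows()
    ]


def write_truth_sidecar(truth: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(truth, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# pipeline driver


def _mean_rate(estimates: list[secondary.RateEstimate]) -> float:
    return float(np.mean([e.value for e in estimates]))


def run_pipeline(config: RunConfig, inputs: dict) -> dict:
    """Execute the workflow stages on whatever inputs are present.

    ``inputs`` may contain 'clear_points' (list of ClearPointTable),
    'solubility' (list of (T, C) points), 'induction' (dict S ->
    InductionDataset), 'counts' (dict S -> [CountSeries]) and 'psd'
    (dict S -> [PSDSeries]).  Returns a consolidated report dict with
    explicit units; stage failures are recorded under 'errors' and
    dependent stages are skipped with an explanation.  Deterministic for
    fixed inputs.
    """
    if not inputs:
        raise ValidationError(["no input datasets supplied"])
    report: dict = {"config": asdict(config), "stages": {}, "errors": {}}
    stages = report["stages"]
    errors = report["errors"]

    if "clear_points" in inputs or "solubility" in inputs:
        try:
            sol_points = list(inputs.get("solubility", []))
            extrapolated = []
            for table in inputs.get("clear_points", []):
                T_eq, ci = core.extrapolate_clear_point(table)
                extrapolated.append(
                    {
                        "concentration_mg_per_g": table.concentration,
                        "solubility_temperature_C": T_eq,
                        "ci_95_C": list(ci),
                    }
                )
                sol_points.append((T_eq, table.concentration))
            model = core.fit_vant_hoff(sol_points) if len(sol_points) >= 2 else None
            stages["solubility"] = {
                "clear_point_extrapolations": extrapolated,
                "vant_hoff": (
                    {
                        "intercept": model.intercept,
                        "slope_K": model.slope_K,
                        "units": "ln(C mg/g) = intercept - slope_K / T(K)",
                    }
                    if model
                    else None
                ),
            }
        except XtalkinError as exc:
            errors["solubility"] = str(exc)

    induction_fits: list[induction.InductionFit] = []
    mit_by_S: dict[float, float] = {}
    if "induction" in inputs:
        rows = []
        skipped = {}
        for S, ds in sorted(inputs["induction"].items()):
            try:
                fit = induction.fit_induction_model(ds)
                induction_fits.append(fit)
                mit_by_S[S] = induction.minimum_induction_time(ds)
                rows.append(
                    {
                        "S": S,
                        "J_per_mL_min": fit.J,
                        "J_stderr": fit.J_stderr,
                        "t_g_min": fit.t_g,
                        "t_g_stderr": fit.t_g_stderr,
                        "MIT_min": mit_by_S[S],
                        "M": fit.M,
                        "n_nucleated": fit.n_nucleated,
                    }
                )
            except XtalkinError as exc:
                skipped[str(S)] = str(exc)
        stages["primary_nucleation"] = {
            "fits": rows,
            "skipped": skipped,
            "units": {"J": "nuclei/(mL min)", "t_g": "min"},
        }
        if skipped and not rows:
            errors["primary_nucleation"] = "no supersaturation could be fitted"

    B_estimates: list[secondary.RateEstimate] = []
    G_estimates: list[secondary.RateEstimate] = []
    delay_by_S: dict[float, list[float]] = {}
    if "counts" in inputs:
        try:
            skipped_vials = {}
            for S, traces in sorted(inputs["counts"].items()):
                for cs in traces:
                    try:
                        window = secondary.select_window(
                            cs, config.window_low, config.window_high
                        )
                    except XtalkinError as exc:
                        skipped_vials[cs.vial_id] = str(exc)
                        continue
                    t, dens = secondary.counts_to_density(cs)
                    B_estimates.append(
                        secondary.estimate_secondary_rate(
                            t, dens, window, supersaturation=S
                        )
                    )
                    delay = secondary.detect_delay_time(cs, config.window_low)
                    if delay is not None:
                        delay_by_S.setdefault(S, []).append(delay)
            stages["secondary_nucleation"] = {
                "skipped": skipped_vials,
                "rates": [
                    {
                        "S": e.supersaturation,
                        "B_per_mL_min": e.value,
                        "stderr": e.stderr,
                        "window_min": list(e.window),
                        "r_squared": e.r_squared,
                    }
                    for e in B_estimates
                ],
                "delay_min_by_S": {
                    str(S): v for S, v in sorted(delay_by_S.items())
                },
                "units": {"B": "particles/(mL min)", "delay": "min"},
            }
        except XtalkinError as exc:
            errors["secondary_nucleation"] = str(exc)

    if "psd" in inputs:
        try:
            count_windows: dict[float, list[tuple[float, float] | None]] = {}
            for S, traces in inputs.get("counts", {}).items():
                wins = []
                for cs in traces:
                    try:
                        wins.append(
                            secondary.select_window(
                                cs, config.window_low, config.window_high
                            )
                        )
                    except XtalkinError:
                        wins.append(None)
                count_windows[S] = wins
            for S, series_list in sorted(inputs["psd"].items()):
                for i, ps in enumerate(series_list):
                    pts = secondary.d90_series(ps)
                    if not pts:
                        continue
                    windows = count_windows.get(S)
                    if windows and i < len(windows) and windows[i] is not None:
                        window = windows[i]
                        # clip to the PSD's own span
                        window = (
                            max(window[0], pts[0][0]),
                            min(window[1], pts[-1][0]),
                        )
                    else:
                        window = (pts[0][0], pts[-1][0])
                    try:
                        G_estimates.append(
                            secondary.estimate_growth_rate(
                                pts, window, supersaturation=S
                            )
                        )
                    except XtalkinError:
                        continue
            stages["growth"] = {
                "rates": [
                    {
                        "S": e.supersaturation,
                        "G_um_per_min": e.value,
                        "stderr": e.stderr,
                        "window_min": list(e.window),
                        "r_squared": e.r_squared,
                    }
                    for e in G_estimates
                ],
                "units": {"G": "um/min"},
            }
        except XtalkinError as exc:
            errors["growth"] = str(exc)

    # power laws across supersaturations
    growth_law = secondary_law = primary_law = None
    power_laws: dict = {}
    by_S_G: dict[float, list[float]] = {}
    for e in G_estimates:
        if e.value > 0:
            by_S_G.setdefault(e.supersaturation, []).append(e.value)
    if len(by_S_G) >= 2:
        growth_law = core.fit_power_law(
            [(S, float(np.mean(v))) for S, v in sorted(by_S_G.items())],
            rate_kind="growth",
        )
        power_laws["growth"] = {
            "k_um_per_min": growth_law.prefactor,
            "n": growth_law.exponent,
            "r_squared": growth_law.r_squared,
        }
    by_S_B: dict[float, list[float]] = {}
    for e in B_estimates:
        if e.value > 0:
            by_S_B.setdefault(e.supersaturation, []).append(e.value)
    if len(by_S_B) >= 2:
        secondary_law = core.fit_power_law(
            [(S, float(np.mean(v))) for S, v in sorted(by_S_B.items())],
            rate_kind="secondary_nucleation",
        )
        power_laws["secondary_nucleation"] = {
            "k_per_mL_min": secondary_law.prefactor,
            "n": secondary_law.exponent,
            "r_squared": secondary_law.r_squared,
        }
    primary_points = [
        (f.supersaturation, f.J) for f in induction_fits if f.J > 0
    ]
    if len(primary_points) >= 2:
        primary_law = core.fit_power_law(
            primary_points, rate_kind="primary_nucleation"
        )
        power_laws["primary_nucleation"] = {
            "k_per_mL_min": primary_law.prefactor,
            "n": primary_law.exponent,
            "r_squared": primary_law.r_squared,
        }
    if power_laws:
        stages["power_laws"] = power_laws

    if growth_law is not None and (induction_fits or delay_by_S):
        try:
            summary = mechanism.MechanismSummary(diagnostics={})
            if induction_fits:
                mit_points = [
                    mechanism.OffsetPoint(
                        supersaturation=f.supersaturation,
                        offset_min=mit_by_S[f.supersaturation],
                        inverse_growth=1.0
                        / float(
                            core.evaluate_power_law(
                                growth_law, f.supersaturation
                            )
                        ),
                    )
                    for f in induction_fits
                ]
                tg_points = [
                    mechanism.OffsetPoint(
                        supersaturation=f.supersaturation,
                        offset_min=f.t_g,
                        inverse_growth=1.0
                        / float(
                            core.evaluate_power_law(
                                growth_law, f.supersaturation
                            )
                        ),
                    )
                    for f in induction_fits
                    if f.t_g > 0
                ]
                if len(mit_points) >= 2:
                    summary.L_sn_mit = mechanism.offset_fit_through_origin(
                        mit_points
                    )
                if len(tg_points) >= 2:
                    summary.L_sn_tg = mechanism.offset_fit_through_origin(
                        tg_points
                    )
            if len(delay_by_S) >= 3:
                delay_points = [
                    (
                        1.0 / float(core.evaluate_power_law(growth_law, S)),
                        float(np.mean(delays)),
                    )
                    for S, delays in sorted(delay_by_S.items())
                ]
                summary.t_min_delay, summary.L_det = (
                    mechanism.delay_fit_free_intercept(delay_points)
                )
            table = (
                mechanism.behavior_table(
                    induction_fits, B_estimates, growth_law
                )
                if (induction_fits or B_estimates)
                else []
            )
            stages["mechanism"] = {
                "L_sn_um_from_MIT": summary.L_sn_mit,
                "L_sn_um_from_t_g": summary.L_sn_tg,
                "t_min_delay_min": summary.t_min_delay,
                "L_det_um": summary.L_det,
                "behavior_table": table,
            }
        except XtalkinError as exc:
            errors["mechanism"] = str(exc)
    elif induction_fits or delay_by_S:
        errors["mechanism"] = (
            "skipped: growth power law unavailable (needs growth rates at "
            ">=2 supersaturations)"
        )

    if config.msmpr_phi is not None:
        try:
            design = msmpr.msmpr_required_rates(
                config.msmpr_phi, config.msmpr_d43_m, config.msmpr_tau_s
            )
            entry = {
                "B_per_mL_min": design.B_per_mL_min,
                "G_um_per_min": design.G_um_per_min,
                "inputs": {
                    "phi": design.phi,
                    "d43_m": design.d43_m,
                    "tau_s": design.tau_s,
                },
            }
            if growth_law is not None and secondary_law is not None:
                entry["operating_point"] = msmpr.operating_point(
                    design, growth_law, secondary_law
                )
            stages["msmpr"] = entry
        except XtalkinError as exc:
            errors["msmpr"] = str(exc)

    return report


def write_report(report: dict, path: str | Path) -> None:
    """Serialise the report deterministically (sorted keys, fixed floats)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, allow_nan=True)
        fh.write("\n")
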