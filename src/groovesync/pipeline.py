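"""End-to-end orchestration: simulate -> kinematics -> synchrony -> table -> statistics.

A :class:`RunConfig` (usually loaded from YAML) drives a deterministic run:
the factorial design is generated, ratings and per-trial latent coupling are
drawn from the structural DGP, head movement is synthesized with the
corresponding phase coupling, PLVs are measured by the analysis pipeline (so
the analysis-facing synchrony columns are measured, not copied from the
ground truth), and the inferential suite is applied.  Every artifact is
written with a checksum manifest; re-running with the same config reproduces
identical tables.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as gio
from . import sem as gsem
from .kinematics import markers_to_angle
from .scoring import assemble  # noqa: F401  (re-exported for CLI convenience)
from .simulate import (
    DesignSpec,
    MovementSimParams,
    RatingDGP,
    default_rating_dgp,
    forward_kinematics,
    generate_design,
    kappa_for_plv,
    simulate_neck_angle,
    simulate_ratings,
)
from .stats import (
    anova_two_way,
    art_anova,
    conditionwise_correlations,
    center_within,
    fit_random_intercept,
    normality_violated,
)
from .synchrony import plv_pipeline

log = logging.getLogger("groovesync")

#: Per-condition movement profiles: amplitude and baseline coupling shifts chosen
#: so mean PLV2 orders Static < Free < Dynamic, as instructed movement implies.
DEFAULT_CONDITION_MOVEMENT: dict[str, dict] = {
    "Free": {"amplitude_1hz": 1.5, "amplitude_2hz": 3.0, "noise_sd": 0.4, "plv_shift": (0.0, 0.0)},
    "Static": {"amplitude_1hz": 0.4, "amplitude_2hz": 0.6, "noise_sd": 0.3, "plv_shift": (-0.04, -0.10)},
    "Dynamic": {"amplitude_1hz": 3.0, "amplitude_2hz": 8.0, "noise_sd": 0.5, "plv_shift": (0.03, 0.12)},
}


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    out_dir: str = "runs/latest"
    seed: int = 0
    design: DesignSpec = field(default_factory=DesignSpec)
    condition_movement: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CONDITION_MOVEMENT.items()}
    )
    frequencies: tuple[float, float] = (1.0, 2.0)
    half_bandwidth_hz: float = 0.3
    edge_trim_s: float = 1.0
    cutoff_hz: float = 5.0
    filter_order: int = 4
    max_gap: int = 10
    kinematics_route: str = "direct"  # 'direct' angle signal or 'markers' full chain
    anova_mode: str = "pooled"
    correction: str = "holm"
    run_sem: bool = True
    run_multigroup: bool = False
    run_lmm: bool = True
    dgp: RatingDGP = field(default_factory=default_rating_dgp)

    def __post_init__(self) -> None:
        if self.kinematics_route not in ("direct", "markers"):
            raise ValueError("kinematics_route must be 'direct' or 'markers'")
        for cond in self.design.movement_conditions:
            if cond not in self.condition_movement:
                raise ValueError(f"no movement profile for condition {cond!r}")


def load_config(path) -> RunConfig:
    """Build a RunConfig from a YAML file (flat keys mirror the dataclass)."""
    raw = gio.load_yaml(path)
    design = DesignSpec(**raw.pop("design", {}))
    known = {f for f in RunConfig.__dataclass_fields__} - {"design", "dgp"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(design=design, **raw)


def _measure_trial_plvs(angle, config: RunConfig) -> dict[str, float]:
    out = {}
    for i, freq in enumerate(config.frequencies, start=1):
        res = plv_pipeline(
            angle,
            freq,
            half_bandwidth_hz=config.half_bandwidth_hz,
            edge_trim_s=config.edge_trim_s,
            filter_order=config.filter_order,
        )
        out[f"plv{i}"] = res.plv
    return out


def simulate_trial_movement(
    row: pd.Series, latent: pd.Series, config: RunConfig, rng: np.random.Generator
):
    """Synthesize one trial's angle signal with coupling set by the latent DGP."""
    profile = config.condition_movement[row["movement"]]
    shift1, shift2 = profile.get("plv_shift", (0.0, 0.0))
    target1 = float(np.clip(latent["plv1"] + shift1, 0.02, 0.98))
    target2 = float(np.clip(latent["plv2"] + shift2, 0.02, 0.98))
    params = MovementSimParams(
        amplitude_1hz=profile.get("amplitude_1hz", 1.5),
        amplitude_2hz=profile.get("amplitude_2hz", 3.0),
        kappa_1hz=kappa_for_plv(target1),
        kappa_2hz=kappa_for_plv(target2),
        broadband_noise_sd=profile.get("noise_sd", 0.3),
    )
    angle = simulate_neck_angle(
        params,
        config.design.trial_duration_s,
        config.design.sampling_rate_hz,
        rng=rng,
    )
    if config.kinematics_route == "markers":
        markers = forward_kinematics(angle)
        angle = markers_to_angle(
            markers,
            cutoff_hz=config.cutoff_hz,
            filter_order=config.filter_order,
            max_gap=config.max_gap,
        )
    return angle


def _anova_suite(table: pd.DataFrame, config: RunConfig) -> dict:
    out = {}
    for dv in ("urge", "pleasure", "plv1", "plv2"):
        agg = (
            table.groupby(["participant", "syncopation", "movement"], observed=True)[dv]
            .mean()
            .reset_index()
        )
        violated = normality_violated(agg, dv, "syncopation", "movement")
        fn = art_anova if violated else anova_two_way
        result = fn(
            table, dv, "syncopation", "movement", mode=config.anova_mode, aggregate=True
        )
        out[dv] = {
            "normality_violated": violated,
            "mode": result.mode,
            "table": result.table.to_dict(orient="records"),
        }
    return out


def _sem_suite(table: pd.DataFrame, config: RunConfig) -> dict:
    spec = gsem.embodied_model_spec()
    out: dict = {"per_condition": {}}
    groups = {}
    for cond, sub in table.groupby("movement", observed=True, sort=False):
        fit = gsem.fit_ml(spec, data=sub)
        groups[cond] = sub
        out["per_condition"][cond] = {
            "chi2": fit.chi2,
            "df": fit.df,
            "cfi": fit.cfi,
            "tli": fit.tli,
            "rmsea": fit.rmsea,
            "srmr": fit.srmr,
            "classification": gsem.classify_fit(fit),
            "paths": fit.params[fit.params.matrix.isin(["B", "Gamma"])][
                ["label", "est", "se", "z", "p", "std_all"]
            ].to_dict(orient="records"),
        }
    if config.run_multigroup and len(groups) >= 2:
        constrained = gsem.fit_multigroup(spec, groups, "paths")
        free = gsem.fit_multigroup(spec, groups, ())
        d_chi2, d_df, p = gsem.chi_square_difference(constrained, free)
        out["multigroup"] = {
            "constrained_chi2": constrained.chi2,
            "free_chi2": free.chi2,
            "delta_chi2": d_chi2,
            "delta_df": d_df,
            "p": p,
        }
    return out


def _lmm_suite(table: pd.DataFrame) -> dict:
    data = center_within(table, "urge")
    fit = fit_random_intercept(
        data, "plv2", "urge_within * C(movement)", unit="participant"
    )
    return {
        "dv": "plv2",
        "formula": "urge_within * C(movement) + (1 | participant)",
        "estimates": fit.summary().reset_index(names="term").to_dict(orient="records"),
        "sigma_b": fit.sigma_b,
        "sigma": fit.sigma,
        "loglik": fit.loglik,
        "converged": fit.converged,
        "at_boundary": fit.at_boundary,
    }


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages and write tables, results, and a checksum manifest.

    Returns the run directory.  Any stage failure aborts with the stage name
    (and trial key where applicable) in the exception message.
    """
    t0 = time.time()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed_seq = np.random.SeedSequence(config.seed)
    n_expected = config.design.n_participants * config.design.trials_per_participant
    children = seed_seq.spawn(n_expected + 1)

    stage = "design"
    try:
        design_spec = DesignSpec(**{**asdict_shallow(config.design), "seed": config.seed})
        design = generate_design(design_spec)

        stage = "ratings"
        table, truth = simulate_ratings(
            design, config.dgp, rng=np.random.default_rng(children[0])
        )

        stage = "movement/synchrony"
        latent = truth.latent
        plv_rows = []
        for i, (idx, row) in enumerate(table.iterrows()):
            try:
                angle = simulate_trial_movement(
                    row, latent.loc[idx], config, np.random.default_rng(children[i + 1])
                )
                plv_rows.append(_measure_trial_plvs(angle, config))
            except Exception as exc:
                key = {k: row[k] for k in ("participant", "movement", "syncopation", "pattern")}
                raise RuntimeError(f"stage {stage} failed at trial {key}: {exc}") from exc
        measured = pd.DataFrame(plv_rows, index=table.index)
        table[["plv1", "plv2"]] = measured[["plv1", "plv2"]]

        stage = "tables"
        gio.write_trial_table(table, out_dir / "trials.csv")
        gio.write_ground_truth(truth, out_dir / "ground_truth.json")

        stage = "statistics"
        results: dict = {"seed": config.seed, "n_trials": len(table)}
        results["anova"] = _anova_suite(table, config)
        results["correlations"] = conditionwise_correlations(table).to_dict(orient="records")
        if config.run_sem:
            results["sem"] = _sem_suite(table, config)
        if config.run_lmm:
            results["lmm"] = _lmm_suite(table)
        results["condition_means"] = (
            table.groupby("movement", observed=True)[["urge", "pleasure", "plv1", "plv2"]]
            .mean()
            .round(6)
            .reset_index()
            .to_dict(orient="records")
        )
        gio.write_json(results, out_dir / "results.json")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "seed": config.seed,
        "elapsed_s": round(time.time() - t0, 3),
        "artifacts": {},
    }
    for path in sorted(out_dir.glob("*")):
        if path.name == "manifest.json" or path.is_dir():
            continue
        manifest["artifacts"][path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
    gio.write_json(manifest, out_dir / "manifest.json")
    log.info("pipeline finished in %.1f s -> %s", time.time() - t0, out_dir)
    return out_dir


def asdict_shallow(spec: DesignSpec) -> dict:
    return {
        "n_participants": spec.n_participants,
        "syncopation_levels": spec.syncopation_levels,
        "patterns_per_level": spec.patterns_per_level,
        "movement_conditions": spec.movement_conditions,
        "tempo_bpm": spec.tempo_bpm,
        "trial_duration_s": spec.trial_duration_s,
        "sampling_rate_hz": spec.sampling_rate_hz,
        "seed": spec.seed,
    }


def validate_inputs(paths) -> dict:
    """Schema and unit sanity report for marker TSVs and trial/rating CSVs.

    Report-only: each file gets ``{"ok": bool, "issues": [...]}`` and nothing
    raises for content problems.
    """
    report: dict[str, dict] = {}
    for p in map(Path, paths):
        issues: list[str] = []
        if not p.exists():
            report[str(p)] = {"ok": False, "issues": ["file not found"]}
            continue
        try:
            if p.suffix.lower() == ".tsv":
                series = gio.read_marker_tsv(p)
                if np.abs(series.positions[np.isfinite(series.positions)]).max() > 10:
                    issues.append("marker coordinates exceed 10 m; wrong units?")
            elif p.suffix.lower() == ".csv":
                frame = pd.read_csv(p, comment="#")
                for col in ("urge", "pleasure"):
                    if col in frame.columns:
                        bad = frame.index[(frame[col] < 0) | (frame[col] > 6)]
                        for row in bad:
                            issues.append(f"{col} out of [0, 6] at row {row}")
                for col in ("plv1", "plv2"):
                    if col in frame.columns:
                        bad = frame.index[(frame[col] < 0) | (frame[col] > 1)]
                        for row in bad:
                            issues.append(f"{col} out of [0, 1] at row {row}")
                item_cols = [c for c in frame.columns if c.startswith("item")]
                for col in item_cols:
                    bad = frame.index[(frame[col] < 0) | (frame[col] > 6)]
                    for row in bad:
                        issues.append(f"{col} out of [0, 6] at row {row}")
            else:
                issues.append(f"unrecognized extension {p.suffix!r}")
        except Exception as exc:
            issues.append(f"schema violation: {exc}")
        report[str(p)] = {"ok": not issues, "issues": issues}
    return report
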