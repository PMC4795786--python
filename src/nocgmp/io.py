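"""Parameter-file I/O, tabular output, and the end-to-end pipeline runner.

Parameter files are flat YAML: the 13 rate-constant keys ``k1``..``k13``,
the 12 species names as initial concentrations, and a ``units`` block
declaring the concentration and time units the values are expressed in.
Values are converted to the package's internal μM/s on load.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .model import (
    BIMOLECULAR,
    DEFAULT_INITIAL_STATE,
    DEFAULT_PARAMETERS,
    InitialState,
    ParameterSet,
    SPECIES,
    ValidationError,
    apply_oxidative_stress,
    simulate,
)
from .perturb import screen
from .combination import (
    CombinationSurface,
    DoseVector,
    RHO_MIN_CONVENTION,
    build_surface,
    classify_isoboles,
    compare_to_bliss,
)

__all__ = [
    "load_parameters",
    "save_parameters",
    "write_trajectory",
    "write_surface",
    "read_surface",
    "RunConfig",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

_CONC_TO_UM = {"M": 1e6, "mM": 1e3, "uM": 1.0, "µM": 1.0, "nM": 1e-3}
_TIME_TO_S = {"h": 3600.0, "min": 60.0, "s": 1.0, "ms": 1e-3}


def load_parameters(path) -> tuple[ParameterSet, InitialState]:
    """Read a parameter/initial-condition file; convert to μM and seconds.

    The file must contain every rate constant k1..k13, every species
    initial concentration, and a ``units`` block; unknown keys are
    rejected. All problems are reported together, naming each offending
    key.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: expected a mapping at the top level")
    units = raw.pop("units", None)
    if not isinstance(units, dict) or "concentration" not in units or "time" not in units:
        raise ValidationError(
            f"{path}: a units block with 'concentration' and 'time' is required"
        )
    cu, tu = units["concentration"], units["time"]
    if cu not in _CONC_TO_UM:
        raise ValidationError(
            f"{path}: unsupported concentration unit {cu!r} "
            f"(supported: {sorted(_CONC_TO_UM)})"
        )
    if tu not in _TIME_TO_S:
        raise ValidationError(
            f"{path}: unsupported time unit {tu!r} (supported: {sorted(_TIME_TO_S)})"
        )
    cf, tf = _CONC_TO_UM[cu], _TIME_TO_S[tu]

    k_keys = [f"k{i}" for i in range(1, 14)]
    expected = set(k_keys) | set(SPECIES)
    problems = []
    missing = [k for k in k_keys + list(SPECIES) if k not in raw]
    if missing:
        problems.append(f"missing keys: {', '.join(missing)}")
    unknown = sorted(set(raw) - expected)
    if unknown:
        problems.append(f"unknown keys: {', '.join(unknown)}")
    bad_value = []
    for key in sorted(set(raw) & expected, key=list(raw).index):
        v = raw[key]
        if isinstance(v, bool) or not isinstance(v, (int, float)):
            bad_value.append(f"{key}={v!r} (non-numeric)")
        elif not np.isfinite(v) or v < 0:
            bad_value.append(f"{key}={v!r} (must be finite and >= 0)")
    if bad_value:
        problems.append(f"invalid values: {'; '.join(bad_value)}")
    if problems:
        raise ValidationError(f"{path}: " + "; ".join(problems))

    k_values = {}
    for i in range(1, 14):
        v = float(raw[f"k{i}"])
        # bimolecular constants are 1/(conc·time); unimolecular are 1/time
        k_values[f"k{i}"] = v / (cf * tf) if i in BIMOLECULAR else v / tf
    species_values = {s: float(raw[s]) * cf for s in SPECIES}
    return ParameterSet.from_dict(k_values), InitialState.from_dict(species_values)


def save_parameters(
    path,
    params: ParameterSet = DEFAULT_PARAMETERS,
    init: InitialState = DEFAULT_INITIAL_STATE,
) -> None:
    """Write a parameter file in the package's native μM/s units."""
    doc: dict = {"units": {"concentration": "uM", "time": "s"}}
    doc.update(params.as_dict())
    doc.update(init.as_dict())
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def write_trajectory(path, result) -> None:
    """Tidy TSV: time column plus one column per species."""
    result.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_surface(path, surface: CombinationSurface) -> None:
    """Long-format TSV: one row per dose-grid cell."""
    df = surface.to_frame()
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_surface(path) -> CombinationSurface:
    """Rebuild a CombinationSurface from its long-format TSV."""
    df = pd.read_csv(path, sep="\t")
    rho_cols = [c for c in df.columns if c.startswith("rho_")]
    if len(rho_cols) not in (2, 3):
        raise ValidationError(f"{path}: expected 2 or 3 rho_* columns, got {rho_cols}")
    targets = tuple(int(c.split("_k")[-1] if "_k" in c else c[4:].lstrip("k"))
                    for c in rho_cols)
    axes = [np.array(sorted(df[c].unique(), reverse=True)) for c in rho_cols]
    shape = tuple(len(a) for a in axes)
    if len(df) != int(np.prod(shape)):
        raise ValidationError(f"{path}: grid is not full-factorial")
    values = np.full(shape, np.nan)
    index = [{v: i for i, v in enumerate(a)} for a in axes]
    for _, row in df.iterrows():
        idx = tuple(index[d][row[c]] for d, c in enumerate(rho_cols))
        values[idx] = row["cgmp_T"]
    if np.isnan(values).any():
        raise ValidationError(f"{path}: grid has missing cells")
    vectors = tuple(
        DoseVector(t, tuple(a)) for t, a in zip(targets, axes)
    )
    return CombinationSurface(
        targets=targets,
        vectors=vectors,
        values=values,
        reference=float(values[(0,) * len(shape)]),
    )


@dataclass(frozen=True)
class RunConfig:
    """Serializable description of one full pipeline run."""

    out_dir: str
    params_path: str | None = None  # None -> frozen calibrated defaults
    h2o2: float = 500.0
    t_end: float = 200.0
    n_points: int = 201
    max_order: int = 3
    rho: float = 0.1
    pairs: tuple[tuple[int, int], ...] = ((1, 3), (1, 10), (3, 10))
    bliss_mode: str = "response-product"
    isobole_levels: tuple[float, ...] = (0.25, 0.5, 0.75)
    isobole_threshold: float = 0.05
    surface_n: int = 11
    seed: int = 0
    make_figures: bool = True
    verbose: bool = False


def _plot_timecourses(path, ctrl_res, h2o2_res):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(ctrl_res.t, ctrl_res.cgmp, label="control")
    ax.plot(h2o2_res.t, h2o2_res.cgmp, label="H$_2$O$_2$")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("cGMP (μM)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _plot_surface(path, surface: CombinationSurface):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if len(surface.targets) != 2:
        return
    fig, ax = plt.subplots(figsize=(4.2, 3.8))
    r1 = np.asarray(surface.vectors[0].ratios)
    r2 = np.asarray(surface.vectors[1].ratios)
    cs = ax.contourf(r2, r1, surface.normalized(), levels=12, cmap="viridis")
    ax.contour(r2, r1, surface.normalized(), levels=8, colors="k", linewidths=0.5)
    fig.colorbar(cs, ax=ax, label="relative cGMP$_T$")
    ax.set_xlabel(f"$\\rho_{{k{surface.targets[1]}}}$")
    ax.set_ylabel(f"$\\rho_{{k{surface.targets[0]}}}$")
    ax.invert_xaxis()
    ax.invert_yaxis()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def run_pipeline(config: RunConfig) -> dict:
    """Execute simulate -> screen -> dose matrices -> Bliss -> isoboles.

    Writes TSV tables, optional figures, the echoed config, and a
    machine-readable summary into ``config.out_dir``. Stage failures are
    logged and recorded in the summary's ``failures`` list; partial
    outputs are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    echo = asdict(config)
    echo["package_version"] = __version__
    (out / "config.json").write_text(json.dumps(echo, indent=2, sort_keys=True) + "\n")

    if config.params_path is None:
        params, init0 = DEFAULT_PARAMETERS, DEFAULT_INITIAL_STATE
    else:
        params, init0 = load_parameters(config.params_path)
    control = apply_oxidative_stress(init0, 0.0)
    stressed = apply_oxidative_stress(init0, config.h2o2)

    summary: dict = {"package_version": __version__, "failures": []}
    t0 = time.perf_counter()

    # stage: baseline dynamics
    try:
        ctrl_res = simulate(params, control, config.t_end, config.n_points)
        h2o2_res = simulate(params, stressed, config.t_end, config.n_points)
        write_trajectory(out / "trajectory_control.tsv", ctrl_res)
        write_trajectory(out / "trajectory_h2o2.tsv", h2o2_res)
        pk_c, tpk_c = ctrl_res.peak_cgmp()
        pk_h, _ = h2o2_res.peak_cgmp()
        summary["control_peak_cgmp"] = pk_c
        summary["control_peak_time"] = tpk_c
        summary["h2o2_peak_cgmp"] = pk_h
        summary["peak_fold_reduction"] = pk_c / pk_h if pk_h > 0 else None
        if config.make_figures:
            _plot_timecourses(out / "timecourses.png", ctrl_res, h2o2_res)
        logger.info("dynamics stage done in %.1f s", time.perf_counter() - t0)
    except Exception as exc:  # pragma: no cover - defensive
        logger.error("dynamics stage failed: %s", exc)
        summary["failures"].append(f"dynamics: {exc}")

    # stage: combinatorial screen
    try:
        t1 = time.perf_counter()
        df = screen(
            params,
            stressed,
            max_order=config.max_order,
            rho=config.rho,
            t_end=config.t_end,
            n_points=config.n_points,
            control_init=control,
        )
        df.to_csv(out / "screen.tsv", sep="\t", index=False, float_format="%.10g")
        ok = df[df["status"] == "ok"]
        summary["n_screened"] = int(len(df))
        summary["n_failed_solves"] = int((df["status"] != "ok").sum())
        summary["top_perturbations"] = ok["targets"].head(10).tolist()
        summary["top_relative_cgmp_T"] = [round(v, 4) for v in
                                          ok["relative_cgmp_T"].head(10)]
        logger.info("screen stage done in %.1f s", time.perf_counter() - t1)
    except Exception as exc:
        logger.error("screen stage failed: %s", exc)
        summary["failures"].append(f"screen: {exc}")

    # stage: dose matrices + Bliss + isoboles for the headline pairs
    summary["bliss"] = {}
    summary["isoboles"] = {}
    for pair in config.pairs:
        name = f"k{pair[0]}_k{pair[1]}"
        try:
            t2 = time.perf_counter()
            surf = build_surface(
                pair,
                params,
                stressed,
                rho_min=RHO_MIN_CONVENTION[2],
                n=config.surface_n,
                t_end=config.t_end,
                n_points=config.n_points,
            )
            write_surface(out / f"surface_{name}.tsv", surf)
            if config.make_figures:
                _plot_surface(out / f"contour_{name}.png", surf)
            bp = compare_to_bliss(
                pair,
                RHO_MIN_CONVENTION[2],
                params,
                stressed,
                control_init=control,
                mode=config.bliss_mode,
                t_end=config.t_end,
                n_points=config.n_points,
            )
            summary["bliss"][name] = {
                "observed_cgmp_T": bp.observed,
                "predicted_cgmp_T": bp.predicted,
                "excess": bp.excess,
            }
            cls = classify_isoboles(
                surf,
                config.isobole_levels,
                threshold=config.isobole_threshold,
            )
            cls.table.to_csv(
                out / f"isoboles_{name}.tsv", sep="\t", index=False,
                float_format="%.6g",
            )
            summary["isoboles"][name] = cls.overall
            logger.info("pair %s done in %.1f s", name, time.perf_counter() - t2)
        except Exception as exc:
            logger.error("combination stage for %s failed: %s", name, exc)
            summary["failures"].append(f"combination {name}: {exc}")

    logger.info("pipeline finished in %.1f s", time.perf_counter() - t0)
    # summary content is a pure function of the config's scientific fields,
    # so identical runs produce byte-identical files
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary
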