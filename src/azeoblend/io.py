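"""Shared readers/writers, configuration, logging and the pipeline driver.

File formats
------------
* Spectra: two-column CSV (``wavenumber_cm-1,absorbance``) or JCAMP-DX
  with fixed-form AFFN ``XYDATA=(X++(Y..Y))``.  The canonical in-memory
  grid is ascending; JCAMP files are written descending (instrument
  convention) with explicit ``FIRSTX``/``LASTX``.
* Configuration: YAML with strict validation -- unknown keys are
  rejected and every numeric field is range-checked at load.
* All writes are atomic (write to a temporary sibling, then rename), so
  re-running a pipeline with identical config and seed yields
  byte-identical machine-readable outputs.
"""

from __future__ import annotations

import json
import logging
import os
import tempfile
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigError, DomainError, FormatError
from .spectra import Spectrum
from .vle import ActivityModel, BinaryVLE, Component

__all__ = [
    "RunConfig",
    "FitConfig",
    "read_spectrum",
    "write_spectrum",
    "load_run_config",
    "reference_config_path",
    "atomic_write_text",
    "setup_logging",
    "run_pipeline",
]

logger = logging.getLogger("azeoblend")


def setup_logging(level: str = "INFO") -> None:
    """Configure package logging: stage banners at INFO, fit detail at DEBUG."""
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


# ---------------------------------------------------------------------------
# atomic writes
# ---------------------------------------------------------------------------


def atomic_write_text(path, text: str) -> None:
    """Write ``text`` to ``path`` via a temporary file and rename."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name, suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


# ---------------------------------------------------------------------------
# spectrum IO
# ---------------------------------------------------------------------------


def write_spectrum(spec: Spectrum, path, format: str = "csv", title: str = "spectrum") -> None:
    """Write a spectrum as two-column CSV or fixed-form JCAMP-DX."""
    path = Path(path)
    if format == "csv":
        lines = ["wavenumber_cm-1,absorbance"]
        lines += [
            f"{float(nu)!r},{float(ab)!r}"
            for nu, ab in zip(spec.wavenumbers, spec.absorbance)
        ]
        atomic_write_text(path, "\n".join(lines) + "\n")
    elif format == "jcamp-dx":
        # descending X, AFFN one X plus up to 6 Y per line
        nu = spec.wavenumbers[::-1]
        ab = spec.absorbance[::-1]
        out = [
            f"##TITLE={title}",
            "##JCAMP-DX=4.24",
            "##DATA TYPE=INFRARED SPECTRUM",
            "##XUNITS=1/CM",
            "##YUNITS=ABSORBANCE",
            f"##FIRSTX={float(nu[0])!r}",
            f"##LASTX={float(nu[-1])!r}",
            f"##NPOINTS={nu.size}",
            "##XFACTOR=1.0",
            "##YFACTOR=1.0",
            "##XYDATA=(X++(Y..Y))",
        ]
        for i in range(0, nu.size, 6):
            ys = " ".join(repr(float(v)) for v in ab[i : i + 6])
            out.append(f"{float(nu[i])!r} {ys}")
        out.append("##END=")
        atomic_write_text(path, "\n".join(out) + "\n")
    else:
        raise FormatError(f"unknown spectrum format {format!r}")


def _read_spectrum_csv(path) -> Spectrum:
    nus, abs_ = [], []
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(",")
            if len(parts) < 2:
                raise FormatError(f"{path}: line {i + 1} is not two-column CSV")
            try:
                nus.append(float(parts[0]))
                abs_.append(float(parts[1]))
            except ValueError:
                if i == 0:
                    continue  # header row
                raise FormatError(f"{path}: non-numeric data at line {i + 1}")
    if len(nus) < 2:
        raise FormatError(f"{path}: fewer than two data rows")
    nu = np.array(nus)
    ab = np.array(abs_)
    if nu[0] > nu[-1]:
        nu, ab = nu[::-1], ab[::-1]
    return Spectrum(nu, ab)


def _read_spectrum_jcamp(path) -> Spectrum:
    header: dict[str, str] = {}
    data_lines: list[str] = []
    in_data = False
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("##"):
                if in_data:
                    break  # ##END or a following block
                key, _, value = line[2:].partition("=")
                header[key.strip().upper()] = value.strip()
                if key.strip().upper() == "XYDATA":
                    in_data = True
            elif in_data and line:
                data_lines.append(line)
    for required in ("FIRSTX", "LASTX", "NPOINTS", "XYDATA"):
        if required not in header:
            raise FormatError(f"{path}: JCAMP header missing ##{required}")
    xfactor = float(header.get("XFACTOR", "1.0"))
    yfactor = float(header.get("YFACTOR", "1.0"))
    npoints = int(header["NPOINTS"])
    nus, abs_ = [], []
    for line in data_lines:
        vals = line.replace(",", " ").split()
        if len(vals) < 2:
            raise FormatError(f"{path}: XYDATA line with fewer than two values")
        x0 = float(vals[0]) * xfactor
        ys = [float(v) * yfactor for v in vals[1:]]
        firstx = float(header["FIRSTX"]) * xfactor
        lastx = float(header["LASTX"]) * xfactor
        step = (lastx - firstx) / (npoints - 1)
        start_index = round((x0 - firstx) / step)
        for j, y in enumerate(ys):
            nus.append(firstx + (start_index + j) * step)
            abs_.append(y)
    if len(nus) != npoints:
        raise FormatError(
            f"{path}: NPOINTS={npoints} but {len(nus)} values decoded"
        )
    nu = np.array(nus)
    ab = np.array(abs_)
    order = np.argsort(nu)
    return Spectrum(nu[order], ab[order])


def read_spectrum(path, format: str | None = None) -> Spectrum:
    """Read a spectrum; the format is inferred from the suffix if omitted.

    Returns the canonical ascending-grid :class:`Spectrum`; descending
    JCAMP data are flipped, uniformity of the grid is enforced by the
    container.
    """
    path = Path(path)
    if format is None:
        format = "jcamp-dx" if path.suffix.lower() in {".jdx", ".dx"} else "csv"
    if format == "csv":
        return _read_spectrum_csv(path)
    if format == "jcamp-dx":
        return _read_spectrum_jcamp(path)
    raise FormatError(f"unknown spectrum format {format!r}")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FitConfig:
    """Settings of the estimation stages."""

    bootstrap_replicates: int = 500
    bootstrap_seed: int | None = None  # derived from the run seed when None
    min_x0_molpct: float = 40.0
    max_pls_components: int = 15
    protection_threshold: float = 0.8
    include_assay: bool = True

    def __post_init__(self) -> None:
        if self.bootstrap_replicates < 1:
            raise ConfigError("bootstrap_replicates must be positive")
        if not 0 <= self.min_x0_molpct <= 100:
            raise ConfigError("min_x0_molpct must lie in [0, 100]")
        if self.max_pls_components < 1:
            raise ConfigError("max_pls_components must be positive")
        if not 0 < self.protection_threshold < 1:
            raise ConfigError("protection_threshold must lie in (0, 1)")


@dataclass(frozen=True)
class RunConfig:
    """Validated top-level configuration of a pipeline run."""

    component_a: Component
    component_b: Component
    activity: ActivityModel
    temperature: float = 323.15
    generator: "object" = None  # GeneratorConfig; late import avoids a cycle
    fit: FitConfig = field(default_factory=FitConfig)

    def __post_init__(self) -> None:
        if self.generator is None:
            from .synthetic_data import GeneratorConfig

            object.__setattr__(self, "generator", GeneratorConfig())
        if not self.temperature > 0:
            raise ConfigError("temperature must be positive (K)")

    def vle(self) -> BinaryVLE:
        return BinaryVLE(
            self.component_a, self.component_b, self.activity, self.temperature
        )


def _check_keys(mapping: dict, allowed: set[str], context: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"unknown keys in {context}: {sorted(unknown)}")


def _parse_component(raw: dict, context: str) -> Component:
    _check_keys(raw, {"name", "molar_mass", "antoine", "t_range"}, context)
    try:
        return Component(
            name=str(raw["name"]),
            molar_mass=float(raw["molar_mass"]),
            antoine=tuple(float(v) for v in raw["antoine"]),
            t_range=tuple(float(v) for v in raw.get("t_range", (273.15, 423.15))),
        )
    except KeyError as exc:
        raise ConfigError(f"{context}: missing field {exc}") from exc
    except DomainError as exc:
        raise ConfigError(f"{context}: {exc}") from exc


def load_run_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    from .synthetic_data import GeneratorConfig

    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    _check_keys(
        raw, {"components", "activity", "temperature", "generator", "fit"}, str(path)
    )
    comps = raw.get("components")
    if not isinstance(comps, dict) or set(comps) != {"a", "b"}:
        raise ConfigError(f"{path}: components must define exactly 'a' and 'b'")
    component_a = _parse_component(comps["a"], "components.a")
    component_b = _parse_component(comps["b"], "components.b")

    act_raw = raw.get("activity", {}) or {}
    _check_keys(act_raw, {"coefficients"}, "activity")
    coeffs = act_raw.get("coefficients", [])
    if not all(isinstance(v, (int, float)) for v in coeffs):
        raise ConfigError("activity.coefficients must be numeric")
    activity = ActivityModel(tuple(float(v) for v in coeffs))

    temperature = float(raw.get("temperature", 323.15))

    gen_raw = raw.get("generator", {}) or {}
    gen_fields = {f.name for f in dc_fields(GeneratorConfig)}
    _check_keys(gen_raw, gen_fields, "generator")
    if "oven_initial_molpct" in gen_raw:
        gen_raw["oven_initial_molpct"] = tuple(
            float(v) for v in gen_raw["oven_initial_molpct"]
        )
        gen_raw.setdefault("n_oven_mixtures", len(gen_raw["oven_initial_molpct"]))
    if "assay_times_h" in gen_raw:
        gen_raw["assay_times_h"] = tuple(float(v) for v in gen_raw["assay_times_h"])
    if "oven_sampling_times_h" in gen_raw:
        gen_raw["oven_sampling_times_h"] = tuple(
            float(v) for v in gen_raw["oven_sampling_times_h"]
        )
    try:
        generator = GeneratorConfig(**gen_raw)
    except (TypeError, DomainError) as exc:
        raise ConfigError(f"generator: {exc}") from exc

    fit_raw = raw.get("fit", {}) or {}
    _check_keys(fit_raw, {f.name for f in dc_fields(FitConfig)}, "fit")
    fit = FitConfig(**fit_raw)

    return RunConfig(
        component_a=component_a,
        component_b=component_b,
        activity=activity,
        temperature=temperature,
        generator=generator,
        fit=fit,
    )


def reference_config_path() -> Path:
    """Path of the shipped IR3535 / nonanoic acid 50 degC fixture config."""
    return Path(__file__).parent / "data" / "ir3535_nonanoic_50C.yaml"


# ---------------------------------------------------------------------------
# pipeline driver
# ---------------------------------------------------------------------------


def run_pipeline(config: RunConfig, outdir, seed: int | None = None) -> dict:
    """Execute the full synthetic-data analysis chain and write a report.

    Stages: equilibrium analysis (azeotrope location/classification) ->
    synthetic oven campaign -> FTIR calibration (PLS1 + LOO selection) ->
    inverse composition identification of the oven samples -> shared
    drift fit with bootstrap CI -> repellence assay fits.  The report is
    written as ``report.json`` (machine-readable, byte-stable for a fixed
    seed) and ``report.txt`` (human summary).
    """
    from .azeofit import DriftDataset, DriftTrajectory, bootstrap_azeotrope, fit_avrami
    from .calibration import fit_pls1, loo_cv_select
    from .evaporation import correct_sampling_losses
    from .repellence import ProtectionCurve, fit_protection_curve, protection_duration
    from .synthetic_data import gen_assay_counts, gen_calibration_set, gen_oven_experiment
    from .repellence import SigmoidFit

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.generator.seed if seed is None else int(seed)
    ss = np.random.SeedSequence(seed)
    seed_cal, seed_oven, seed_boot, seed_assay = (
        int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(4)
    )
    report: dict = {"seed": seed, "temperature_K": config.temperature, "stages": []}

    logger.info("stage vle: locating azeotropes")
    from .vle import find_azeotropes

    vle = config.vle()
    points = find_azeotropes(vle)
    report["vle"] = {
        "azeotropes": [
            {
                "x_a_molpct": p.x_a_molpct,
                "pressure_pa": p.pressure,
                "sign": p.sign,
                "stability": p.stability,
            }
            for p in points
        ],
        "p_sat_a_pa": vle.p_sat_a,
        "p_sat_b_pa": vle.p_sat_b,
    }
    report["stages"].append("vle")

    logger.info("stage generator: oven campaign and calibration set")
    oven = gen_oven_experiment(
        config.generator, vle, rng=np.random.default_rng(seed_oven)
    )
    cal = gen_calibration_set(config.generator, rng=np.random.default_rng(seed_cal))
    report["evaporation"] = {
        "n_trajectories": len(oven.trajectories),
        "terminal_x_a_molpct": [
            float(100.0 * t.x_a[-1]) for t in oven.trajectories
        ],
    }
    report["stages"].append("evaporation")

    logger.info("stage calibration: PLS1 with LOO direction selection")
    cv = loo_cv_select(cal, config.fit.max_pls_components)
    model = fit_pls1(cal, cv.chosen)
    report["calibration"] = {
        "n_training_mixtures": len(cal),
        "chosen_components": cv.chosen,
        "loo_mean_error_molpct": cv.mean_error_at_chosen,
        "loo_max_error_molpct": cv.max_error_at_chosen,
    }
    report["stages"].append("calibration")

    logger.info("stage azeofit: inverse identification + drift regression")
    drift_trajs = []
    for i, (x0_molpct, log, specs) in enumerate(
        zip(oven.initial_molpct, oven.mass_logs, oven.spectra)
    ):
        loss = correct_sampling_losses(log)
        mass0 = log.gross_mass[0]
        released = (loss["evaporative_loss_g"] / mass0).to_numpy()[1:]
        preds = model.predict_matrix(
            np.vstack([s.absorbance for s in specs])
        ) if specs else np.array([])
        keep = released < 1.0
        drift_trajs.append(
            DriftTrajectory(
                x0_molpct=float(x0_molpct),
                released=np.concatenate([[0.0], released[keep]]),
                x_molpct=np.concatenate(
                    [[float(x0_molpct)], np.clip(preds[keep], 0.0, 100.0)]
                ),
            )
        )
    drift = DriftDataset(tuple(drift_trajs))
    fit = fit_avrami(drift, min_x0=config.fit.min_x0_molpct)
    boot_seed = (
        config.fit.bootstrap_seed if config.fit.bootstrap_seed is not None else seed_boot
    )
    boot = bootstrap_azeotrope(
        fit, n_replicates=config.fit.bootstrap_replicates, seed=boot_seed
    )
    report["azeofit"] = {
        "estimate_molpct": boot.estimate,
        "ci_low_molpct": boot.ci_low,
        "ci_high_molpct": boot.ci_high,
        "n_replicates": boot.n_replicates,
        "bootstrap_seed": boot_seed,
        "n_trajectories_fit": len(fit.data),
    }
    report["stages"].append("azeofit")

    if config.fit.include_assay:
        logger.info("stage repellence: assay generation and sigmoid fits")
        truths = {
            "blend": SigmoidFit(p_max=0.98, t50=5.0, s=0.5, rmse=0.0, flags=frozenset()),
            "IR3535": SigmoidFit(p_max=0.95, t50=3.8, s=0.8, rmse=0.0, flags=frozenset()),
            "DEET": SigmoidFit(p_max=0.98, t50=3.2, s=0.25, rmse=0.0, flags=frozenset()),
        }
        assay_rng = np.random.default_rng(seed_assay)
        rep_out = {}
        for name, truth in truths.items():
            counts = gen_assay_counts(
                truth, config.generator, rng=assay_rng, treatment=name
            )
            pooled = counts.groupby("time_h")[
                ["treated_probes", "control_probes"]
            ].sum()
            curve = ProtectionCurve.from_counts(
                pooled.index.to_numpy(),
                pooled["treated_probes"].to_numpy(),
                pooled["control_probes"].to_numpy(),
            )
            sig = fit_protection_curve(curve)
            try:
                duration = protection_duration(sig, config.fit.protection_threshold)
            except DomainError:
                duration = None
            rep_out[name] = {
                "p_max": sig.p_max,
                "t50_h": sig.t50,
                "s_h": sig.s,
                "rmse": sig.rmse,
                "flags": sorted(sig.flags),
                f"duration_at_{config.fit.protection_threshold}_h": duration,
            }
        report["repellence"] = rep_out
        report["stages"].append("repellence")
    else:
        report["repellence"] = "skipped"
        logger.info("stage repellence: skipped (no assay section)")

    atomic_write_text(outdir / "report.json", json.dumps(report, sort_keys=True, indent=2) + "\n")
    atomic_write_text(outdir / "report.txt", _human_summary(report))
    return report


def _human_summary(report: dict) -> str:
    lines = ["azeoblend pipeline report", "=" * 26, f"seed: {report['seed']}"]
    lines.append("")
    lines.append("Azeotropes (mol% IR3535, Pa, sign, stability):")
    for az in report["vle"]["azeotropes"]:
        lines.append(
            f"  {az['x_a_molpct']:7.3f}  {az['pressure_pa']:8.4f}  "
            f"{az['sign']:8s}  {az['stability']}"
        )
    c = report["calibration"]
    lines.append("")
    lines.append(
        f"PLS1 calibration: {c['chosen_components']} directions "
        f"(LOO mean {c['loo_mean_error_molpct']:.3f} / "
        f"max {c['loo_max_error_molpct']:.3f} mol%)"
    )
    a = report["azeofit"]
    lines.append(
        f"Azeotrope composition estimate: {a['estimate_molpct']:.1f} mol% "
        f"(95% CI {a['ci_low_molpct']:.1f}, {a['ci_high_molpct']:.1f}; "
        f"B={a['n_replicates']})"
    )
    if report["repellence"] == "skipped":
        lines.append("Repellence stage skipped.")
    else:
        lines.append("")
        lines.append("Protection fits:")
        for name, r in report["repellence"].items():
            dur_key = next(k for k in r if k.startswith("duration_at_"))
            dur = r[dur_key]
            dur_s = f"{dur:.2f} h" if dur is not None else "n/a"
            lines.append(
                f"  {name:8s} P_max={r['p_max']:.3f} t50={r['t50_h']:.2f} h "
                f"s={r['s_h']:.2f} h protection>{dur_key.split('_')[2]}: {dur_s}"
            )
    return "\n".join(lines) + "\n"
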