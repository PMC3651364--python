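"""End-to-end cohort runs: simulate two-visit subjects, reconstruct,
analyze curves and peaks, build colour maps and reproducibility tables.

Every source of randomness derives from one root seed through spawned seed
sequences, so re-running with the same configuration is bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .acquisition import AcquisitionParams
from .cohort import PhaseTemplate, build_colour_grid, group_average, normalize_curve
from .curves import (
    DIRECTIONS,
    detect_end_systole,
    detect_phase_markers,
    detect_peaks,
    e_over_a,
    summarize_peaks,
)
from .geometry import (
    assign_segments,
    compute_geometry,
    erode_geometry_mask,
    region_average,
    to_cylindrical,
)
from .io import colour_grid_to_csv, curves_to_frame
from .phantom import (
    annulus_contours,
    build_motion_model,
    encode_phases,
    generate_stationary_series,
    random_background_coeffs,
    render_velocity_frames,
)
from .plots import render_bland_altman, render_colour_grid
from .repro import bland_altman, reproducibility_table
from .velocity import reconstruct_velocities


@dataclass
class CohortConfig:
    """Study conditions for a synthetic cohort run."""

    n_subjects: int = 10
    slice_level: str = "mid"
    grid_size: int = 128
    seed: int = 1
    noise_sd: float = 0.05  # rad, phase noise per set
    background_scale: float = 0.08  # rad, background polynomial coefficient sd
    amplitude_jitter: float = 0.10  # relative between-subject amplitude sd
    time_jitter_ms: tuple = (10.0, 25.0)  # systolic, diastolic peak-time sd
    es_time_mean: float = 349.0  # ms
    es_time_sd: float = 25.0  # ms
    rr_mean: float = 994.0  # ms
    rr_sd: float = 60.0  # ms
    rr_range: tuple = (813.0, 1226.0)  # ms
    rr_day2_delta: float | None = None  # ms; None draws day 2 independently
    two_visits: bool = True
    n_phases: int = 60
    median_kernel: int = 5
    peak_smooth_window: int = 1
    marker_smooth_window: int = 1
    boundary_guard_px: int = 1  # erode analysis mask against partial volume
    modulation_amp: float = 0.3
    template_sections: tuple = (350.0, 150.0, 300.0, 200.0)
    acquisition: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be at least 1")
        if self.noise_sd < 0 or self.background_scale < 0:
            raise ValueError("noise and background scales must be non-negative")
        self.time_jitter_ms = tuple(float(v) for v in self.time_jitter_ms)
        self.rr_range = tuple(float(v) for v in self.rr_range)
        self.template_sections = tuple(float(v) for v in self.template_sections)
        if len(self.template_sections) != 4:
            raise ValueError("template_sections must give the four section lengths")

    @property
    def template(self) -> PhaseTemplate:
        s, e, d, a = self.template_sections
        return PhaseTemplate(s, e, d, a, self.n_phases)

    def params(self, rr_interval: float) -> AcquisitionParams:
        return AcquisitionParams(**{"rr_interval": rr_interval, **self.acquisition})

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))


@dataclass
class SubjectDayResult:
    subject: int
    day: int
    rr_interval: float
    t_end_systole_prescribed: float
    markers: object
    peaksets: dict
    summary: pd.DataFrame
    global_curves: dict
    normalized_seg24: dict
    ground_truth: object
    e_over_a: dict


@dataclass
class CohortResult:
    config: CohortConfig
    subjects: list  # list of SubjectDayResult
    repro: pd.DataFrame | None
    colour_grids: dict


def _seed_int(seed_seq) -> int:
    return int(seed_seq.generate_state(1)[0] % (2**31))


def simulate_subject_day(
    config: CohortConfig, rr: float, tes: float, model_seed: int, acq_seeds
):
    """Simulate one visit: motion model, encoded series, stationary phantom."""
    params = config.params(rr)
    model = build_motion_model(
        config.slice_level,
        seed=model_seed,
        params=params,
        rr_interval=rr,
        t_end_systole=tes,
        amplitude_jitter=config.amplitude_jitter,
        time_jitter_ms=config.time_jitter_ms,
        modulation_amp=config.modulation_amp,
    )
    rendered = render_velocity_frames(model, params, grid_size=config.grid_size)
    bg = random_background_coeffs(acq_seeds[0], scale=config.background_scale)
    rendered.ground_truth.background_coeffs = bg
    encoded = encode_phases(
        rendered.truth,
        params,
        background_coeffs=bg,
        noise_sd=config.noise_sd,
        seed=acq_seeds[1],
        magnitude=rendered.magnitude,
    )
    stationary = generate_stationary_series(
        params,
        grid_size=config.grid_size,
        frame_times=rendered.truth.frame_times,
        rr_interval=rr,
        background_coeffs=bg,
        noise_sd=config.noise_sd,
        seed=acq_seeds[2],
    )
    return model, rendered, encoded, stationary


def analyze_subject_day(config, model, encoded, stationary, subject, day, gt):
    """Reconstruct velocities and quantify global and 24-segment motion."""
    rr = model.rr_interval
    params = config.params(rr)
    field_series = reconstruct_velocities(
        encoded, stationary, rr, config.n_phases, config.median_kernel
    )
    endo, epi, landmark, _ = annulus_contours(model, field_series.frame_times)
    geom = compute_geometry(
        endo, epi, landmark, config.grid_size, params.pixel_spacing, config.slice_level
    )
    if config.boundary_guard_px:
        geom = erode_geometry_mask(geom, config.boundary_guard_px)
    cyl = to_cylindrical(field_series, geom)
    global_curves = region_average(cyl)

    t_es = detect_end_systole(global_curves["radial"], config.marker_smooth_window)
    markers = detect_phase_markers(
        global_curves["radial"], t_es, smooth_window=config.marker_smooth_window
    )
    peaksets = {
        d: detect_peaks(
            global_curves[d],
            d,
            config.slice_level,
            markers,
            smooth_window=config.peak_smooth_window,
        )
        for d in DIRECTIONS
    }
    summary = pd.concat(
        [summarize_peaks(peaksets[d], markers) for d in DIRECTIONS], ignore_index=True
    )
    ratios = {}
    for d, label in (("longitudinal", "EA_L"), ("radial", "EA_R")):
        dp, ap = peaksets[d].get("D"), peaksets[d].get("AS")
        if dp is not None and ap is not None and ap.amplitude != 0:
            ratios[label] = e_over_a(dp.amplitude, ap.amplitude)

    seg24 = assign_segments(geom, "equal24")
    normalized = {d: [] for d in DIRECTIONS}
    for i in range(24):
        seg_curves = region_average(cyl, seg24, segment=i)
        for d in DIRECTIONS:
            normalized[d].append(
                normalize_curve(seg_curves[d], markers, config.template)
            )
    return SubjectDayResult(
        subject=subject,
        day=day,
        rr_interval=rr,
        t_end_systole_prescribed=model.t_end_systole,
        markers=markers,
        peaksets=peaksets,
        summary=summary,
        global_curves=global_curves,
        normalized_seg24=normalized,
        ground_truth=gt,
        e_over_a=ratios,
    )


def run_cohort(config: CohortConfig, out_dir=None) -> CohortResult:
    """Generate and analyze a full two-visit synthetic cohort.

    With `out_dir` set, writes tidy curve/peak CSVs, 24-segment colour grids
    (CSV + PNG), the reproducibility table, Bland-Altman plots and a run
    log; whatever completed before a failure is preserved on disk.
    """
    root = np.random.SeedSequence(config.seed)
    subject_seqs = root.spawn(config.n_subjects)
    results: list[SubjectDayResult] = []
    log = {"version": __version__, "seed": config.seed, "subjects": []}
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out / "config.yaml")

    try:
        for s, sseq in enumerate(subject_seqs):
            draw, model_seq, day1_seq, day2_seq = sseq.spawn(4)
            rng = np.random.default_rng(draw)
            rr1 = float(
                np.clip(rng.normal(config.rr_mean, config.rr_sd), *config.rr_range)
            )
            tes = float(np.clip(rng.normal(config.es_time_mean, config.es_time_sd),
                                200.0, 500.0))
            if config.rr_day2_delta is not None:
                sign = 1.0 if s % 2 == 0 else -1.0
                rr2 = float(np.clip(rr1 + sign * config.rr_day2_delta, *config.rr_range))
            else:
                rr2 = float(
                    np.clip(rng.normal(config.rr_mean, config.rr_sd), *config.rr_range)
                )
            model_seed = _seed_int(model_seq)
            days = [(1, rr1, day1_seq)]
            if config.two_visits:
                days.append((2, rr2, day2_seq))
            for day, rr, dseq in days:
                acq_seeds = [_seed_int(q) for q in dseq.spawn(3)]
                stage = "simulate"
                try:
                    model, rendered, encoded, stationary = simulate_subject_day(
                        config, rr, tes, model_seed, acq_seeds
                    )
                    stage = "analyze"
                    res = analyze_subject_day(
                        config, model, encoded, stationary, s, day,
                        rendered.ground_truth,
                    )
                except Exception as exc:
                    raise RuntimeError(
                        f"stage {stage!r} failed for subject {s} day {day}"
                    ) from exc
                results.append(res)
                log["subjects"].append(
                    {"subject": s, "day": day, "rr_ms": rr, "t_end_systole_ms": tes,
                     "seeds": acq_seeds}
                )
    finally:
        if out is not None and results:
            _write_outputs(config, results, out, log)

    repro = None
    if config.two_visits and config.n_subjects >= 2:
        day1 = {r.subject: r.summary for r in results if r.day == 1}
        day2 = {r.subject: r.summary for r in results if r.day == 2}
        repro = reproducibility_table(day1, day2)
        if out is not None:
            repro.to_csv(out / "reproducibility.csv", index=False)
            _bland_altman_plots(results, out)

    grids = _colour_grids(config, results)
    if out is not None:
        for d, grid in grids.items():
            colour_grid_to_csv(grid, out / f"colour_grid_{d}.csv")
            render_colour_grid(grid, out / f"colour_grid_{d}.png")
        (out / "run_log.json").write_text(json.dumps(log, indent=1))
    return CohortResult(config=config, subjects=results, repro=repro, colour_grids=grids)


def _colour_grids(config, results):
    grids = {}
    day1 = [r for r in results if r.day == 1]
    if not day1:
        return grids
    for d in DIRECTIONS:
        seg_means = []
        for i in range(24):
            mean, _sd = group_average([r.normalized_seg24[d][i] for r in day1])
            mean.region = f"seg{i + 1:02d}"
            seg_means.append(mean)
        grids[d] = build_colour_grid(seg_means, d, config.slice_level, config.template)
    return grids


def _write_outputs(config, results, out, log):
    peaks = []
    curve_frames = []
    for r in results:
        df = r.summary.copy()
        df.insert(0, "subject", r.subject)
        df.insert(1, "day", r.day)
        df["rr_ms"] = r.rr_interval
        for label, value in r.e_over_a.items():
            df.attrs[label] = value
        peaks.append(df)
        cf = curves_to_frame(r.global_curves.values())
        cf.insert(0, "subject", r.subject)
        cf.insert(1, "day", r.day)
        curve_frames.append(cf)
    pd.concat(peaks, ignore_index=True).to_csv(out / "peaks.csv", index=False)
    pd.concat(curve_frames, ignore_index=True).to_csv(
        out / "global_curves.csv", index=False
    )
    ea_rows = [
        {"subject": r.subject, "day": r.day, "parameter": k, "value": v}
        for r in results
        for k, v in r.e_over_a.items()
    ]
    pd.DataFrame(ea_rows).to_csv(out / "e_over_a.csv", index=False)


def _bland_altman_plots(results, out):
    day1 = {r.subject: r for r in results if r.day == 1}
    day2 = {r.subject: r for r in results if r.day == 2}
    common = sorted(set(day1) & set(day2))
    for scale in ("ttp_ms", "ttp_fixed_ms"):
        v1, v2 = [], []
        for s in common:
            a = day1[s].summary.set_index("peak")
            b = day2[s].summary.set_index("peak")
            if "AS_L" in a.index and "AS_L" in b.index:
                v1.append(float(a.loc["AS_L", scale]))
                v2.append(float(b.loc["AS_L", scale]))
        if len(v1) >= 2:
            res = bland_altman(np.column_stack([v1, v2]))
            render_bland_altman(
                res, out / f"bland_altman_AS_L_{scale}.png",
                title=f"TTP AS_L ({scale.replace('_', ' ')})",
            )
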