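"""End-to-end study orchestration.

Simulates (or ingests) per-animal data for each study group, runs the
beat/variability/metabolic stages, aggregates to group mean +/- SEM,
applies the Levene/ANOVA/SNK statistics layer, and renders study-style
summary tables where each group's value carries markers naming the
reference groups it differs from (the † / ¥ convention generalized to
"differs from group k").

Two simulation modes exist.  ``beats`` (default) generates the beat
series directly from the tachogram model — the downstream analysis path
is identical, and the waveform rendering/detection stage is validated
separately by its round-trip tests.  ``waveform`` renders full
pressure waveforms and runs the detector, exercising the whole chain at
higher cost; in this mode pulse amplitudes are constant within an
animal, so pressure-variability indices are near zero by construction.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .beats import BeatSeries, PressureWaveform, detect_beats, extract_segments, summarize_hemodynamics
from .groupstats import GroupSummary, levene_test, oneway_anova, snk_posthoc
from .metabolic import IntakeRecord, caloric_intake, compute_kitt
from .synthetic import CohortSpec, PulseShapeSpec, TachogramSpec, render_waveform, simulate_itt, simulate_tachogram
from .variability import BAND_PRESETS, analyze_variability

__all__ = [
    "GroupConfig",
    "StudyConfig",
    "StudyReport",
    "run_study",
    "render_report",
    "parse_report",
    "example_study_config",
]

log = logging.getLogger("hemovar.pipeline")

MARKER_SYMBOLS = "†¥§‡*"  # † ¥ § ‡ *


@dataclass(frozen=True)
class GroupConfig:
    """One study group: either simulator parameters or waveform paths.

    ``(mean, sd)`` pairs describe the between-animal distribution of
    each parameter; draws of physical quantities are truncated at zero.
    """

    name: str
    n: int = 8
    sap: tuple[float, float] = (174.0, 14.1)
    dap: tuple[float, float] = (121.0, 19.8)
    hr: tuple[float, float] = (352.0, 36.8)
    pi_mod: dict = field(default_factory=lambda: {"amp_lf": 2.5, "amp_hf": 3.5, "noise_sd": 6.7})
    sap_mod: dict = field(default_factory=lambda: {"amp_lf": 3.2, "amp_hf": 1.0, "noise_sd": 5.1})
    itt: dict = field(default_factory=lambda: {"g0": (83.0, 14.1), "kitt": (4.15, 0.74), "noise_sd": 2.0})
    intake: dict = field(default_factory=lambda: {"chow": (16.8, 6.2), "fluid": (25.2, 0.6), "fructose_conc": 0.0})
    variables: dict = field(default_factory=dict)
    correlations: list = field(default_factory=list)
    waveform_files: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "n": self.n,
            "sap": list(self.sap),
            "dap": list(self.dap),
            "hr": list(self.hr),
            "pi_mod": dict(self.pi_mod),
            "sap_mod": dict(self.sap_mod),
            "itt": {k: (list(v) if isinstance(v, (tuple, list)) else v) for k, v in self.itt.items()},
            "intake": {k: (list(v) if isinstance(v, (tuple, list)) else v) for k, v in self.intake.items()},
            "variables": {k: list(v) for k, v in self.variables.items()},
            "correlations": [list(c) for c in self.correlations],
            "waveform_files": list(self.waveform_files),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroupConfig":
        kw = dict(d)
        for key in ("sap", "dap", "hr"):
            if key in kw:
                kw[key] = tuple(kw[key])
        for key in ("itt", "intake"):
            if key in kw:
                kw[key] = {
                    k: (tuple(v) if isinstance(v, (list, tuple)) else v)
                    for k, v in kw[key].items()
                }
        if "variables" in kw:
            kw["variables"] = {k: tuple(v) for k, v in kw["variables"].items()}
        if "correlations" in kw:
            kw["correlations"] = [tuple(c) for c in kw["correlations"]]
        return cls(**kw)


@dataclass(frozen=True)
class StudyConfig:
    groups: tuple[GroupConfig, ...]
    seed: int = 0
    alpha: float = 0.05
    band_preset: str = "table2"
    duration: float = 960.0
    seg_len: float = 300.0
    n_seg: int = 3
    itt_window: tuple[float, float] = (4.0, 16.0)
    mode: str = "beats"
    sampling_rate: float = 2000.0
    save_intermediate: bool = False

    def __post_init__(self) -> None:
        names = [g.name for g in self.groups]
        if len(names) != len(set(names)):
            raise ValueError("group names must be unique")
        if self.mode not in ("beats", "waveform"):
            raise ValueError("mode must be 'beats' or 'waveform'")
        if self.band_preset not in BAND_PRESETS:
            raise ValueError(f"unknown band preset {self.band_preset!r}")

    def to_dict(self) -> dict:
        return {
            "groups": [g.to_dict() for g in self.groups],
            "seed": self.seed,
            "alpha": self.alpha,
            "band_preset": self.band_preset,
            "duration": self.duration,
            "seg_len": self.seg_len,
            "n_seg": self.n_seg,
            "itt_window": list(self.itt_window),
            "mode": self.mode,
            "sampling_rate": self.sampling_rate,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        kw = dict(d)
        kw.pop("save_intermediate", None)
        kw["groups"] = tuple(GroupConfig.from_dict(g) for g in kw["groups"])
        if "itt_window" in kw:
            kw["itt_window"] = tuple(kw["itt_window"])
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass(frozen=True)
class StudyReport:
    """Aggregated study results.

    ``summary`` has one row per (variable, group) with mean/SEM/n and a
    ``differs_from`` column naming reference groups with a significant
    SNK difference (empty unless the variable's ANOVA p <= alpha).
    ``stats`` has one row per variable with Levene/ANOVA results.
    """

    summary: pd.DataFrame
    stats: pd.DataFrame
    animals: pd.DataFrame
    failures: list
    provenance: dict

    def report_hash(self) -> str:
        blob = render_report(self, "csv").encode()
        return hashlib.sha256(blob).hexdigest()


def _draw(rng: np.random.Generator, mean_sd, lo: float | None = None) -> float:
    m, s = mean_sd
    v = float(rng.normal(m, s))
    if lo is not None:
        v = max(v, lo)
    return v


def _modulated(base: float, mod: dict, t: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = (
        base
        + mod.get("amp_lf", 0.0) * np.sin(2 * np.pi * mod.get("freq_lf", 0.4) * t)
        + mod.get("amp_hf", 0.0) * np.sin(2 * np.pi * mod.get("freq_hf", 1.5) * t)
    )
    noise = mod.get("noise_sd", 0.0)
    if noise > 0:
        out = out + noise * rng.standard_normal(len(t))
    return out


def _simulate_animal(
    group: GroupConfig, config: StudyConfig, seed_seq: np.random.SeedSequence
) -> dict:
    """Simulate one animal and run every analysis stage on it."""
    child = seed_seq.generate_state(4) % (2**31)
    rng = np.random.default_rng(int(child[0]))

    hr = _draw(rng, group.hr, lo=120.0)
    sap = _draw(rng, group.sap, lo=60.0)
    dap = _draw(rng, group.dap, lo=20.0)
    if dap >= sap - 10.0:
        dap = sap - 10.0
    base_pi = 60000.0 / hr

    tacho = simulate_tachogram(
        TachogramSpec(
            base_pi=base_pi,
            amp_lf=group.pi_mod.get("amp_lf", 0.0),
            freq_lf=group.pi_mod.get("freq_lf", 0.4),
            amp_hf=group.pi_mod.get("amp_hf", 0.0),
            freq_hf=group.pi_mod.get("freq_hf", 1.5),
            noise_sd=group.pi_mod.get("noise_sd", 0.0),
            duration=config.duration,
            seed=int(child[1]),
        )
    )

    if config.mode == "waveform":
        wave = render_waveform(
            tacho, PulseShapeSpec(sap=sap, dap=dap, sampling_rate=config.sampling_rate)
        )
        beats = detect_beats(wave)
    else:
        times = tacho.times
        pi = np.empty(len(times))
        pi[0] = np.nan
        pi[1:] = np.diff(times) * 1000.0
        sap_series = _modulated(sap, group.sap_mod, times, rng)
        dap_series = np.full(len(times), dap)
        map_series = dap_series + (sap_series - dap_series) / 3.0
        beats = BeatSeries(times=times, sap=sap_series, dap=dap_series, map=map_series, pi=pi)

    hemo = summarize_hemodynamics(beats)
    segments = extract_segments(beats, seg_len=config.seg_len, n_seg=config.n_seg)
    hrv, bpv = analyze_variability(segments, config.band_preset)

    record = {
        "sap_mmhg": hemo.sap,
        "dap_mmhg": hemo.dap,
        "map_mmhg": hemo.map,
        "hr_bpm": hemo.hr,
        "pi_sd_ms": hrv.sd,
        "pi_var_ms2": hrv.var,
        "pi_lf_ms2": hrv.lf,
        "pi_hf_ms2": hrv.hf,
        "sap_var_mmhg2": bpv.var,
        "sap_lf_mmhg2": bpv.lf,
    }

    if group.itt:
        g0 = _draw(rng, group.itt.get("g0", (100.0, 0.0)), lo=40.0)
        kitt_true = _draw(rng, group.itt.get("kitt", (4.0, 0.0)), lo=0.2)
        curve = simulate_itt(
            g0=g0,
            k=kitt_true / 100.0,
            noise_sd=group.itt.get("noise_sd", 0.0),
            seed=int(child[2]),
        )
        record["kitt_pct_min"] = compute_kitt(curve, window=config.itt_window).kitt
        record["glucose_mg_dl"] = float(curve.glucose[0])

    if group.intake:
        rec = IntakeRecord(
            chow=_draw(rng, group.intake.get("chow", (0.0, 0.0)), lo=0.0),
            fluid=_draw(rng, group.intake.get("fluid", (0.0, 0.0)), lo=0.0),
            fructose_conc=group.intake.get("fructose_conc", 0.0),
        )
        record["kcal_day"] = caloric_intake(rec).total_kcal

    return record


def _ingest_animal(path: str, config: StudyConfig) -> dict:
    wave = PressureWaveform.read(path, sampling_rate=config.sampling_rate)
    beats = detect_beats(wave)
    hemo = summarize_hemodynamics(beats)
    segments = extract_segments(beats, seg_len=config.seg_len, n_seg=config.n_seg)
    hrv, bpv = analyze_variability(segments, config.band_preset)
    return {
        "sap_mmhg": hemo.sap,
        "dap_mmhg": hemo.dap,
        "map_mmhg": hemo.map,
        "hr_bpm": hemo.hr,
        "pi_sd_ms": hrv.sd,
        "pi_var_ms2": hrv.var,
        "pi_lf_ms2": hrv.lf,
        "pi_hf_ms2": hrv.hf,
        "sap_var_mmhg2": bpv.var,
        "sap_lf_mmhg2": bpv.lf,
    }


def run_study(config: StudyConfig, out_dir: str | Path | None = None) -> StudyReport:
    """Run the full study pipeline.

    Deterministic for a fixed config (all randomness derives from
    ``config.seed``).  A failure in one animal's processing is logged
    and excludes that animal (the group n in the report decrements);
    it never aborts the run.
    """
    t_start = time.perf_counter()
    root = np.random.SeedSequence(config.seed)
    group_seqs = root.spawn(len(config.groups))
    rows = []
    failures: list[dict] = []

    for gi, group in enumerate(config.groups):
        group_seq = group_seqs[gi]
        n_animals = len(group.waveform_files) or group.n
        animal_seqs = group_seq.spawn(n_animals)
        cohort_extra = None
        if group.variables:
            cohort_extra = _extra_variables(group, config)
        for ai in range(n_animals):
            label = f"{group.name}-{ai + 1}"
            t0 = time.perf_counter()
            try:
                if group.waveform_files:
                    rec = _ingest_animal(group.waveform_files[ai], config)
                else:
                    rec = _simulate_animal(group, config, animal_seqs[ai])
                if cohort_extra is not None:
                    rec.update(cohort_extra[ai])
                rec.update(animal=label, group=group.name)
                rows.append(rec)
                log.info("animal %s done in %.2fs", label, time.perf_counter() - t0)
            except Exception as exc:  # stage isolation: drop the animal only
                failures.append({"animal": label, "group": group.name, "error": str(exc)})
                log.warning("animal %s failed: %s", label, exc)

    animals = pd.DataFrame(rows)
    if animals.empty:
        raise RuntimeError("every animal failed; no data to aggregate")
    summary, stats = _aggregate(animals, config)

    provenance = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "hemovar_version": __version__,
        "n_animals": int(len(animals)),
        "n_failures": len(failures),
        "elapsed_s": round(time.perf_counter() - t_start, 3),
    }
    report = StudyReport(
        summary=summary, stats=stats, animals=animals, failures=failures, provenance=provenance
    )
    if out_dir is not None:
        _persist(report, config, Path(out_dir))
    return report


def _extra_variables(group: GroupConfig, config: StudyConfig) -> list[dict]:
    """Draw the per-animal cohort variables (assay-style outcomes with
    optional correlation structure)."""
    spec = CohortSpec(
        group_name=group.name,
        means={k: v[0] for k, v in group.variables.items()},
        sds={k: v[1] for k, v in group.variables.items()},
        n=group.n,
        correlations=list(group.correlations),
        seed=(config.seed * 131071 + zlib.crc32(group.name.encode()) % 65521) % (2**31),
    )
    table = simulate_cohort_frame(spec)
    out: list[dict] = [{} for _ in range(group.n)]
    for var in group.variables:
        vals = table[table["variable"] == var].sort_values("animal", key=_animal_order)[
            "value"
        ].to_numpy()
        for i in range(group.n):
            out[i][var] = float(vals[i])
    return out


def _animal_order(s: pd.Series) -> pd.Series:
    return s.str.rsplit("-", n=1).str[-1].astype(int)


def simulate_cohort_frame(spec: CohortSpec) -> pd.DataFrame:
    from .synthetic import simulate_cohort

    return simulate_cohort(spec)


def _aggregate(animals: pd.DataFrame, config: StudyConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    group_order = [g.name for g in config.groups]
    variables = [c for c in animals.columns if c not in ("animal", "group")]
    sum_rows, stat_rows = [], []
    for var in variables:
        per_group: dict[str, np.ndarray] = {}
        for g in group_order:
            vals = animals.loc[(animals["group"] == g), var].dropna().to_numpy()
            if len(vals) >= 2:
                per_group[g] = vals
        summaries = [GroupSummary.from_values(g, per_group[g]) for g in per_group]
        sig_from: dict[str, list[str]] = {g: [] for g in per_group}
        if len(summaries) >= 2:
            try:
                lw, lp = levene_test(list(per_group.values()))
                an = oneway_anova(groups=list(per_group.values()))
                post = (
                    snk_posthoc(summaries, an.ms_within, an.df_within, alpha=config.alpha)
                    if an.p <= config.alpha
                    else None
                )
                stat_rows.append(
                    {
                        "variable": var,
                        "levene_w": lw,
                        "levene_p": lp,
                        "f": an.f,
                        "df_between": an.df_between,
                        "df_within": an.df_within,
                        "p": an.p,
                        "ms_within": an.ms_within,
                    }
                )
                if post is not None:
                    names = list(per_group)
                    for i, g in enumerate(names):
                        for ref in names[:i]:
                            if post.is_significant(g, ref):
                                sig_from[g].append(ref)
            except ValueError as exc:
                log.warning("statistics failed for %s: %s", var, exc)
        for g in per_group:
            s = GroupSummary.from_values(g, per_group[g])
            sum_rows.append(
                {
                    "variable": var,
                    "group": g,
                    "mean": s.mean,
                    "sem": s.sem,
                    "n": s.n,
                    "differs_from": "|".join(sig_from[g]),
                }
            )
    return pd.DataFrame(sum_rows), pd.DataFrame(stat_rows)


def render_report(report: StudyReport, format: str = "csv") -> str:
    """Render the study report as a delimited or Markdown artifact.

    ``csv``: the summary table (stable column order, parseable back via
    :func:`parse_report`).  ``markdown``: study-style table with one row
    per variable, ``mean ± SEM`` cells and per-reference-group marker
    symbols, plus the statistics table and provenance block.
    """
    if format == "csv":
        cols = ["variable", "group", "mean", "sem", "n", "differs_from"]
        return report.summary[cols].to_csv(index=False)
    if format == "markdown":
        return _render_markdown(report)
    raise ValueError(f"unknown report format {format!r}")


def parse_report(text: str) -> pd.DataFrame:
    """Parse a CSV rendering back into the summary data frame."""
    import io

    df = pd.read_csv(io.StringIO(text))
    df["differs_from"] = df["differs_from"].fillna("")
    return df


def _render_markdown(report: StudyReport) -> str:
    groups = list(dict.fromkeys(report.summary["group"]))
    sym = {g: MARKER_SYMBOLS[i] if i < len(MARKER_SYMBOLS) else f"[{i}]" for i, g in enumerate(groups)}
    lines = ["| Variable | " + " | ".join(f"{g} (mean ± SEM)" for g in groups) + " |"]
    lines.append("|" + "---|" * (len(groups) + 1))
    for var in dict.fromkeys(report.summary["variable"]):
        cells = []
        for g in groups:
            row = report.summary[
                (report.summary["variable"] == var) & (report.summary["group"] == g)
            ]
            if row.empty:
                cells.append("—")
                continue
            r = row.iloc[0]
            marks = "".join(sym[ref] for ref in r["differs_from"].split("|") if ref)
            cells.append(f"{r['mean']:.4g} ± {r['sem']:.2g}{marks}")
        lines.append(f"| {var} | " + " | ".join(cells) + " |")
    legend = ", ".join(f"{sym[g]} P ≤ alpha vs {g}" for g in groups[:-1])
    lines.append("")
    lines.append(f"Markers: {legend}.")
    lines.append("")
    if not report.stats.empty:
        lines.append(report.stats.to_markdown(index=False, floatfmt=".4g"))
        lines.append("")
    lines.append(f"Provenance: `{json.dumps(report.provenance, sort_keys=True)}`")
    return "\n".join(lines) + "\n"


def _persist(report: StudyReport, config: StudyConfig, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    report.summary.to_csv(out_dir / "summary.csv", index=False)
    report.stats.to_csv(out_dir / "stats.csv", index=False)
    report.animals.to_csv(out_dir / "animals.csv", index=False)
    (out_dir / "report.md").write_text(render_report(report, "markdown"))
    (out_dir / "provenance.json").write_text(json.dumps(report.provenance, indent=2, sort_keys=True))
    if report.failures:
        (out_dir / "failures.json").write_text(json.dumps(report.failures, indent=2))


def example_study_config(
    seed: int = 0,
    mode: str = "beats",
    duration: float = 960.0,
    n: int = 8,
) -> StudyConfig:
    """The bundled three-group study configuration.

    Groups H (hypertensive), HO (hypertensive ovariectomized) and FHO
    (hypertensive ovariectomized + fructose) are parameterized from the
    bundled reference summaries: between-animal SD = SEM*sqrt(8), PI and
    SAP modulation amplitudes chosen so the injected band powers match
    the reference LF/HF values (amp = sqrt(2*power)) with beat-domain
    white noise making up the remaining total variance.
    """
    from . import datasets

    hemo = datasets.hemodynamics_summary()
    met = datasets.metabolic_summary()
    infl = datasets.inflammation_summary()
    intake = datasets.intake_records()
    intake_sems = {"H": (2.2, 0.2), "HO": (2.9, 3.0), "FHO": (0.5, 1.4)}

    def ms(table, var, g):
        row = table[(table["variable"] == var) & (table["group"] == g)].iloc[0]
        return float(row["mean"]), float(row["sem"] * np.sqrt(row["n"]))

    groups = []
    for g in datasets.GROUPS:
        lf = ms(hemo, "pi_lf_ms2", g)[0]
        hf = ms(hemo, "pi_hf_ms2", g)[0]
        var_tot = ms(hemo, "pi_var_ms2", g)[0]
        s_lf = ms(hemo, "sap_lf_mmhg2", g)[0]
        s_var = ms(hemo, "sap_var_mmhg2", g)[0]
        chow_sem, fluid_sem = intake_sems[g]
        groups.append(
            GroupConfig(
                name=g,
                n=n,
                sap=ms(hemo, "sap_mmhg", g),
                dap=ms(hemo, "dap_mmhg", g),
                hr=ms(hemo, "hr_bpm", g),
                pi_mod={
                    "amp_lf": float(np.sqrt(2 * lf)),
                    "amp_hf": float(np.sqrt(2 * hf)),
                    "noise_sd": float(np.sqrt(max(var_tot - lf - hf, 0.25))),
                },
                sap_mod={
                    "amp_lf": float(np.sqrt(2 * s_lf)),
                    "amp_hf": 0.5,
                    "noise_sd": float(np.sqrt(max(s_var - s_lf, 0.25))),
                },
                itt={
                    "g0": ms(met, "glucose_mg_dl", g),
                    "kitt": ms(met, "kitt_pct_min", g),
                    "noise_sd": 2.0,
                },
                intake={
                    "chow": (intake[g]["chow"], float(chow_sem * np.sqrt(8))),
                    "fluid": (intake[g]["fluid"], float(fluid_sem * np.sqrt(8))),
                    "fructose_conc": intake[g]["fructose_conc"],
                },
                variables={
                    "adipose_tissue_g": ms(met, "adipose_tissue_g", g),
                    "il10_pg_mg": ms(infl, "il10_pg_mg", g),
                    "tnf_alpha_pg_mg": ms(infl, "tnf_alpha_pg_mg", g),
                },
                correlations=[("adipose_tissue_g", "il10_pg_mg", -0.6)],
            )
        )
    return StudyConfig(groups=tuple(groups), seed=seed, mode=mode, duration=duration)
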