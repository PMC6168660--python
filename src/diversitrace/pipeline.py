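"""End-to-end orchestration: simulate/load -> preprocess -> score -> analyze.

The three statistical models are

* ``speed``   — Friedman omnibus over the five presentation speeds
                (65/83/100/117/135%) plus a repeated-measures Bayes factor;
* ``meaning`` — Friedman over {100%, backward, resting-state} with Wilcoxon
                post hocs, Holm correction and paired JZS Bayes factors;
* ``time``    — session-order quartiles (Q1-Q4) irrespective of condition,
                Friedman omnibus plus post hocs.

Per-subject condition summaries are means of the normalized scores over the
subject's non-rejected epochs.  Normalizing displays to the 100% condition
(subtracting each subject's 100% value) is a plotting transform only and is
never applied before testing.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io, stats, synthgen
from .diversity import lzc_epoch, lzs_epoch
from .errors import ChannelError, DesignError
from .preprocess import (
    default_filter_bank,
    epoch_segments,
    fir_filter_bank,
    reject_epochs_auto,
    rereference_and_interpolate,
    resample_half,
)
from .stats import ConditionMatrix, TopographyResult
from .synthgen import MEANING_CONDITIONS, SPEED_CONDITIONS, GeneratorConfig, build_design
from .types import EpochSet, RawRecording

MODELS = ("speed", "meaning", "time")

load_recording = io.load_recording


# ------------------------------------------------------------------- scoring

def score_epochs(
    epochs: EpochSet,
    measures: tuple[str, ...] = ("lzs", "lzc"),
    n_surrogates: int = 1,
    seed: int = 0,
    include_rejected: bool = False,
) -> pd.DataFrame:
    """Score every (kept) epoch; returns the long score table.

    LZs contributes one row per channel plus a channel-mean row
    (``channel='ALL'``, measure ``LZs_mean``); LZc contributes a single
    ``channel='ALL'`` row per epoch.  Surrogate shuffles are seeded
    deterministically per (epoch, measure).
    """
    rows = []
    base = np.random.SeedSequence(seed)
    for e in range(epochs.n_epochs):
        if epochs.rejected[e] and not include_rejected:
            continue
        lab = epochs.labels.iloc[e]
        common = dict(
            subject=lab["subject"],
            epoch=e,
            session_order=int(lab["session_order"]),
            condition=str(lab["condition"]),
        )
        ep_seed = np.random.SeedSequence((seed, e))
        if "lzs" in measures:
            res = lzs_epoch(
                epochs.data[e], n_surrogates=n_surrogates,
                seed=ep_seed.generate_state(1)[0] & 0x7FFFFFFF, epoch_id=e,
            )
            for name, score in zip(epochs.ch_names, res.per_channel):
                rows.append(
                    {**common, "channel": name, "measure": "LZs_channel",
                     "raw": score.raw_count, "surrogate": score.surrogate_count,
                     "normalized": score.normalized,
                     "degenerate_flag": int(score.degenerate_flag)}
                )
            rows.append(
                {**common, "channel": "ALL", "measure": "LZs_mean",
                 "raw": np.nan, "surrogate": np.nan,
                 "normalized": res.channel_mean, "degenerate_flag": 0}
            )
        if "lzc" in measures:
            score = lzc_epoch(
                epochs.data[e], n_surrogates=n_surrogates,
                seed=(ep_seed.generate_state(2)[1] & 0x7FFFFFFF), epoch_id=e,
            )
            rows.append(
                {**common, "channel": "ALL", "measure": "LZc",
                 "raw": score.raw_count, "surrogate": score.surrogate_count,
                 "normalized": score.normalized,
                 "degenerate_flag": int(score.degenerate_flag)}
            )
    return pd.DataFrame(rows, columns=io.SCORE_COLUMNS)


# -------------------------------------------------------------------- models

@dataclass
class StatReport:
    """Omnibus + post hocs + Bayes factors for one statistical model."""

    model: str
    measure: str
    conditions: list[str]
    omnibus: dict
    normality: list[dict]
    posthoc: list[dict]
    bf_omnibus: dict
    n_subjects: int

    def to_dict(self) -> dict:
        return asdict(self)


def condition_matrix(
    scores: pd.DataFrame, conditions: list[str], measure: str = "LZs_mean",
    aggregator: str = "mean",
) -> ConditionMatrix:
    """Per-subject condition summaries (mean over epochs) as a complete matrix."""
    sub = scores[(scores["measure"] == measure) & (scores["channel"].astype(str) == "ALL")]
    sub = sub[sub["condition"].astype(str).isin([str(c) for c in conditions])]
    agg = getattr(
        sub.groupby(["subject", "condition"])["normalized"], aggregator
    )().unstack("condition")
    missing = [c for c in conditions if c not in agg.columns]
    if missing or agg.isna().any().any():
        raise DesignError(
            f"scores incomplete for conditions {missing or 'some subjects'}"
        )
    agg = agg[[str(c) for c in conditions]]
    return ConditionMatrix(agg.to_numpy(), [str(c) for c in conditions], measure)


def _analyze_matrix(
    cm: ConditionMatrix, model: str, posthoc: bool, seed: int
) -> StatReport:
    chi2, df, p = stats.friedman_test(cm)
    normality = [
        dict(zip(("statistic", "p", "decision"),
                 stats.check_normality(cm.values[:, j])), condition=c)
        for j, c in enumerate(cm.conditions)
    ]
    bf = stats.bf_one_way_rm(cm, seed=seed)
    report = StatReport(
        model=model,
        measure=cm.measure,
        conditions=cm.conditions,
        omnibus={"statistic": chi2, "df": df, "p": p,
                 "test": "friedman", "significant": bool(p < 0.05)},
        normality=normality,
        posthoc=[],
        bf_omnibus={"bf10": bf.bf10, "mc_se": bf.mc_se,
                    "band": stats.interpret_bf(bf.bf10)},
        n_subjects=cm.values.shape[0],
    )
    if posthoc:
        pairs = list(itertools.combinations(range(len(cm.conditions)), 2))
        raw_p, entries = [], []
        for i, j in pairs:
            z, pw = stats.wilcoxon_signed_rank(cm.values[:, i], cm.values[:, j])
            bf_pair = stats.jzs_bf_paired(cm.values[:, i], cm.values[:, j])
            raw_p.append(pw)
            entries.append(
                {"pair": [cm.conditions[i], cm.conditions[j]], "z": z, "p_raw": pw,
                 "bf10": bf_pair, "bf_band": stats.interpret_bf(bf_pair)}
            )
        adjusted = stats.holm_adjust(raw_p)
        for entry, adj in zip(entries, adjusted):
            entry["p_holm"] = float(adj)
            entry["significant"] = bool(adj < 0.05)
        report.posthoc = entries
    return report


def run_model(
    scores: pd.DataFrame,
    model: str,
    measure: str = "LZs_mean",
    seed: int = 0,
) -> StatReport:
    """Run one of the study's three statistical models on a score table."""
    if model == "speed":
        cm = condition_matrix(scores, SPEED_CONDITIONS, measure)
        return _analyze_matrix(cm, model, posthoc=False, seed=seed)
    if model == "meaning":
        cm = condition_matrix(scores, MEANING_CONDITIONS, measure)
        return _analyze_matrix(cm, model, posthoc=True, seed=seed)
    if model == "time":
        cm = quartile_matrix(scores, measure)
        return _analyze_matrix(cm, model, posthoc=True, seed=seed)
    raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")


def normalize_display(cm: ConditionMatrix, reference: str = "100") -> np.ndarray:
    """Display transform: subtract each subject's reference-condition value.

    Used for plotting per-subject condition profiles relative to a baseline
    condition.  Never applied before statistical testing (the tests operate
    on the raw per-subject summaries; a common within-subject shift leaves
    ranks and paired differences unchanged anyway).
    """
    if reference not in cm.conditions:
        raise DesignError(f"reference condition {reference!r} not in matrix")
    ref = cm.values[:, cm.conditions.index(reference)]
    return cm.values - ref[:, None]


def quartile_matrix(scores: pd.DataFrame, measure: str = "LZs_mean") -> ConditionMatrix:
    """Subject x quartile means: epochs ordered by session time, split Q1-Q4."""
    sub = scores[(scores["measure"] == measure) & (scores["channel"].astype(str) == "ALL")]
    if sub.empty:
        raise DesignError(f"no rows for measure {measure!r}")
    mats = []
    for _, grp in sub.groupby("subject"):
        q = stats.quartile_split(grp["session_order"].to_numpy())
        means = grp.groupby(q)["normalized"].mean()
        if len(means) < 4:
            raise DesignError("a subject has an empty session-time quartile")
        mats.append(means.sort_index().to_numpy())
    return ConditionMatrix(np.vstack(mats), ["Q1", "Q2", "Q3", "Q4"], measure)


def run_topography(
    scores: pd.DataFrame,
    pair: tuple[str, str] = ("resting-state", "100"),
    positions: np.ndarray | None = None,
    ch_names: list[str] | None = None,
    **kwargs,
) -> tuple[TopographyResult, pd.DataFrame]:
    """Cluster-permutation topography of a per-channel LZs condition contrast.

    Returns the test result plus a per-channel table (mean per condition and
    difference) suitable for topographic plotting.
    """
    sub = scores[(scores["measure"] == "LZs_channel")]
    sub = sub[sub["condition"].astype(str).isin(pair)]
    if ch_names is None:
        ch_names = sorted(sub["channel"].unique())
    per = (
        sub.groupby(["subject", "condition", "channel"])["normalized"]
        .mean()
        .unstack("channel")[ch_names]
    )
    a = per.xs(pair[0], level="condition")
    b = per.xs(pair[1], level="condition")
    if not a.index.equals(b.index):
        raise DesignError("both conditions must cover the same subjects")
    diff = a.to_numpy() - b.to_numpy()
    result = stats.cluster_permutation_test(diff, positions=positions, **kwargs)
    table = pd.DataFrame(
        {
            "channel": ch_names,
            f"mean_{pair[0]}": a.mean(axis=0).to_numpy(),
            f"mean_{pair[1]}": b.mean(axis=0).to_numpy(),
            "mean_diff": result.mean_diff,
            "t": result.t_values,
        }
    )
    return result, table


# -------------------------------------------------------------------- cohort

def simulate_subject(
    subject: int,
    cohort_seed: int = 0,
    conditions: list[str] | None = None,
    presentations_per_condition: int = 4,
    presentation_duration_s: float = 90.0,
    sampling_rate_hz: float = 250.0,
    n_channels: int = 64,
    cfg: GeneratorConfig | None = None,
    effects: dict | None = None,
    drift_slope: float = 0.0,
) -> RawRecording:
    """One synthetic subject: seeded session with optional planted effects."""
    seed = int(np.random.SeedSequence((cohort_seed, subject)).generate_state(1)[0] & 0x7FFFFFFF)
    design = build_design(
        conditions=conditions,
        presentations_per_condition=presentations_per_condition,
        presentation_duration_s=presentation_duration_s,
        sampling_rate_hz=sampling_rate_hz,
        n_channels=n_channels,
        seed=seed,
    )
    if cfg is None:
        cfg = GeneratorConfig()
    from dataclasses import replace

    cfg = replace(cfg, seed=seed, drift_slope=drift_slope)
    rec = synthgen.generate_session(design, cfg)
    if effects:
        rec = synthgen.inject_condition_effects(rec, effects)
    rec.meta["subject"] = subject
    return rec


def cohort_scores(
    n_subjects: int = 19,
    cohort_seed: int = 0,
    measures: tuple[str, ...] = ("lzs",),
    epoch_length_s: float = 10.0,
    n_surrogates: int = 1,
    **subject_kwargs,
) -> pd.DataFrame:
    """Simulate and score a whole cohort (no filtering: the generator's
    output is clean and already at the target rate)."""
    frames = []
    for s in range(n_subjects):
        rec = simulate_subject(s, cohort_seed=cohort_seed, **subject_kwargs)
        epochs = epoch_segments(rec, epoch_length_s=epoch_length_s, subject=s)
        frames.append(
            score_epochs(
                epochs, measures=measures, n_surrogates=n_surrogates,
                seed=int(np.random.SeedSequence((cohort_seed, s, 1)).generate_state(1)[0] & 0x7FFFFFFF),
            )
        )
    return pd.concat(frames, ignore_index=True)


# -------------------------------------------------------------------- report

REPORT_SCHEMA = {
    "required": ["config", "seed", "models"],
    "model_required": ["model", "measure", "conditions", "omnibus",
                       "normality", "posthoc", "bf_omnibus", "n_subjects"],
}


def validate_report_bundle(bundle: dict) -> None:
    for key in REPORT_SCHEMA["required"]:
        if key not in bundle:
            raise ValueError(f"report bundle missing key {key!r}")
    for name, rep in bundle["models"].items():
        for key in REPORT_SCHEMA["model_required"]:
            if key not in rep:
                raise ValueError(f"model report {name!r} missing key {key!r}")


def condition_descriptives(scores: pd.DataFrame) -> list[dict]:
    """Per condition x measure summary of the normalized scores."""
    g = scores[scores["channel"].astype(str) == "ALL"].groupby(
        ["measure", "condition"]
    )["normalized"]
    out = []
    for (measure, condition), vals in g:
        out.append(
            {"measure": measure, "condition": str(condition),
             "mean": float(vals.mean()), "sd": float(vals.std(ddof=1)),
             "n_epochs": int(vals.size)}
        )
    return out


def make_report(
    reports: dict[str, StatReport],
    config: dict | None = None,
    seed: int = 0,
    out_dir=None,
    descriptives: list[dict] | None = None,
) -> tuple[dict, str]:
    """Bundle model reports into JSON + a short markdown summary."""
    if not reports:
        raise ValueError("at least one model report is required")
    bundle = {
        "config": config or {},
        "seed": seed,
        "models": {name: rep.to_dict() for name, rep in reports.items()},
        "descriptives": descriptives or [],
    }
    validate_report_bundle(bundle)
    lines = ["# Signal-diversity report", ""]
    for name, rep in reports.items():
        om = rep.omnibus
        lines.append(f"## Model: {name} ({rep.measure})")
        lines.append(
            f"- Friedman chi2({om['df']}) = {om['statistic']:.3f}, p = {om['p']:.4f}"
            f" ({'significant' if om['significant'] else 'not significant'})"
        )
        bf = rep.bf_omnibus
        lines.append(
            f"- Omnibus BF10 = {bf['bf10']:.3g} (+/- {bf['mc_se']:.2g} MC): {bf['band']}."
        )
        for entry in rep.posthoc:
            lines.append(
                f"- {entry['pair'][0]} vs {entry['pair'][1]}: Z = {entry['z']:.2f}, "
                f"p(Holm) = {entry['p_holm']:.4f}; BF10 = {entry['bf10']:.3g} "
                f"({entry['bf_band']})."
            )
        lines.append("")
    markdown = "\n".join(lines)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(json.dumps(bundle, indent=1))
        (out_dir / "report.md").write_text(markdown)
    return bundle, markdown


# ------------------------------------------------------------------ full run

@dataclass
class RunConfig:
    """Resolved configuration of one end-to-end run (YAML-serializable)."""

    input_paths: list[str] = field(default_factory=list)
    simulate_subjects: int = 0
    seed: int = 0
    apply_filters: bool = True
    epoch_length_s: float = 10.0
    amp_threshold_uv: float = 100.0
    flat_threshold_uv: float = 0.1
    reference: str = "linked_ears"
    measures: tuple[str, ...] = ("lzs",)
    n_surrogates: int = 1
    models: tuple[str, ...] = ("speed", "meaning", "time")
    measure_for_models: str = "LZs_mean"
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        import yaml

        d = asdict(self)
        d["measures"] = list(self.measures)
        d["models"] = list(self.models)
        Path(path).write_text(yaml.safe_dump(d))


def preprocess_recording(rec: RawRecording, config: RunConfig) -> EpochSet:
    if config.apply_filters:
        rec = fir_filter_bank(rec, default_filter_bank())
        rec = resample_half(rec)
    epochs = epoch_segments(rec, config.epoch_length_s,
                            subject=rec.meta.get("subject", 0))
    epochs = reject_epochs_auto(epochs, config.amp_threshold_uv,
                                config.flat_threshold_uv)
    if config.reference in ("average", "linked_ears"):
        try:
            epochs = rereference_and_interpolate(epochs, scheme=config.reference)
        except ChannelError:
            # montages without ear electrodes fall back to the average reference
            epochs = rereference_and_interpolate(epochs, scheme="average")
    return epochs


def run_pipeline(config: RunConfig) -> dict:
    """Full run: simulate or load, preprocess, score, analyze, report."""
    recordings = []
    if config.simulate_subjects:
        for s in range(config.simulate_subjects):
            recordings.append(simulate_subject(
                s, cohort_seed=config.seed,
                sampling_rate_hz=500.0 if config.apply_filters else 250.0,
            ))
    for p in config.input_paths:
        recordings.append(load_recording(p))
    frames = []
    for s, rec in enumerate(recordings):
        rec.meta.setdefault("subject", s)
        epochs = preprocess_recording(rec, config)
        frames.append(score_epochs(
            epochs, measures=config.measures,
            n_surrogates=config.n_surrogates, seed=config.seed + s,
        ))
    scores = pd.concat(frames, ignore_index=True)
    reports = {
        m: run_model(scores, m, measure=config.measure_for_models, seed=config.seed)
        for m in config.models
    }
    bundle, markdown = make_report(
        reports, config=asdict(config), seed=config.seed, out_dir=config.out_dir
    )
    if config.out_dir:
        io.write_scores(scores, Path(config.out_dir) / "scores.tsv")
    return bundle
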