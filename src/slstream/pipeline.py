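"""End-to-end orchestration: streams -> 2-AFC -> synthetic cohort -> ERP ->
inference, from a single seeded configuration.

Every random draw is governed by a named seed so any stage can be replayed
in isolation; a rerun with an identical configuration writes byte-identical
tables.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .afc import make_foils, make_trials, foil_tp, score
from .audio import write_events_tsv
from .lexicon import CONDITIONS, SYLLABARIES, DesignError, rotate_lists
from .montage import CHANNELS_66, REDUCED_MONTAGE
from .erp import COMPONENTS, epoch, evoked, peak_table, preprocess, reject
from .sequence import StreamSpec, generate_sequence, place_chirps, validate_stream
from .stats import anova_table, mixed_rm_anova, one_sample_t
from .stream_stats import (
    empirical_tp,
    empirical_within_tp,
    entropy,
    stream_report,
    theoretical_tp,
    theoretical_within_tp,
)
from .synthetic import (
    DEFAULT_GROUP_SIZES,
    TASKS,
    default_erp_effects,
    default_responder_params,
    simulate_eeg,
    simulate_responses,
)


@dataclass
class RunConfig:
    """Configuration of a full synthetic experiment run."""

    conditions: tuple[str, ...] = CONDITIONS
    syllabary: str = "A"
    mixed_variant: str = "A"
    list_index: int = 0  # counterbalancing list (0-3)
    group_sizes: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    seeds: dict = field(
        default_factory=lambda: {
            "stream": 11,
            "chirps": 23,
            "trials": 37,
            "responder": 53,
            "eeg": 71,
        }
    )
    chirp_hit_rate: float = 0.98
    noise_rms_uv: float = 10.0
    artifact_rate: float = 0.05
    n_eeg_per_group: int = 0  # 0 disables the ERP stage
    eeg_montage: str = "full"  # "full" (64+2) or "reduced" (ROI+2)
    output_dir: str | None = None

    def __post_init__(self) -> None:
        for name in ("stream", "chirps", "trials", "responder", "eeg"):
            if name not in self.seeds:
                raise DesignError(f"missing seed {name!r}")
        for cond, n in self.group_sizes.items():
            if n < 2:
                raise DesignError(f"group {cond} needs >= 2 participants")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "conditions" in raw:
            raw["conditions"] = tuple(raw["conditions"])
        return cls(**raw)


@dataclass
class RunBundle:
    """In-memory artifact bundle of a completed run."""

    config: RunConfig
    streams: dict  # condition -> StreamSequence
    words: dict  # condition -> list[TripletWord]
    foils: dict  # condition -> list[Foil]
    stream_reports: pd.DataFrame
    responses: pd.DataFrame
    accuracy: pd.DataFrame  # per participant x condition x task (x tp_class)
    behavioral_summary: pd.DataFrame
    effects: pd.DataFrame
    chance_tests: pd.DataFrame
    erp_peaks: pd.DataFrame | None
    manifest: dict


def _log(stage: str, t0: float, **info) -> None:
    elapsed = time.perf_counter() - t0
    details = " ".join(f"{k}={v}" for k, v in info.items())
    print(f"[slstream] stage={stage} elapsed={elapsed:.2f}s {details}")


def run_experiment(config: RunConfig) -> RunBundle:
    """Run all stages and (optionally) write the artifact bundle to disk."""
    syllabary = SYLLABARIES[config.syllabary]
    streams, words_by_cond, foils_by_cond = {}, {}, {}
    reports = []
    t0 = time.perf_counter()
    for ci, cond in enumerate(config.conditions):
        try:
            lists = rotate_lists(syllabary, cond, mixed_variant=config.mixed_variant)
            words = lists[config.list_index]
            spec = StreamSpec(condition=cond, seed=config.seeds["stream"] + ci)
            seq = generate_sequence(words, spec)
            seq = place_chirps(seq, seed=config.seeds["chirps"] + ci)
            violations = validate_stream(seq)
            if violations:
                raise DesignError(f"stream validator: {violations[:3]}")
            streams[cond] = seq
            words_by_cond[cond] = words
            foils_by_cond[cond] = make_foils(
                words, syllabary, cond, seed=config.seeds["trials"] + ci
            )
            reports.append(stream_report(seq, words, cond))
        except DesignError as exc:
            raise DesignError(
                f"stage=streams condition={cond} seed={config.seeds['stream'] + ci}: {exc}"
            ) from exc
    stream_reports = pd.concat(reports, ignore_index=True)
    _log("streams", t0, conditions=len(streams))

    # 2-AFC trial lists and synthetic responses
    t0 = time.perf_counter()
    params = default_responder_params(seed=config.seeds["responder"])
    params = type(params)(
        p_correct=params.p_correct,
        chirp_hit_rate=config.chirp_hit_rate,
        n_participants=dict(config.group_sizes),
        seed=config.seeds["responder"],
    )
    trial_lists = {}
    pid = 0
    for cond in config.conditions:
        for _ in range(config.group_sizes.get(cond, 0)):
            for task in TASKS:
                trial_lists[(pid, cond, task)] = make_trials(
                    words_by_cond[cond],
                    foils_by_cond[cond],
                    seed=config.seeds["trials"] * 1000 + pid * 10 + (task == "explicit"),
                )
            pid += 1
    responses = simulate_responses(params, trial_lists)
    _log("cohort", t0, participants=pid, trials=len(responses))

    # scoring
    t0 = time.perf_counter()
    acc_rows = []
    for (p, cond, task), tl in trial_lists.items():
        sub = responses[
            (responses.participant == p)
            & (responses.condition == cond)
            & (responses.task == task)
        ].sort_values("trial")
        sc = score(
            tl,
            list(sub.response),
            chirp_detection_rate=float(sub.chirp_detection_rate.iloc[0]),
        )
        row = {
            "participant": p,
            "condition": cond,
            "task": task,
            "percent_correct": sc.percent_correct,
            "chirp_detection_rate": sc.chirp_detection_rate,
            "excluded": sc.excluded,
        }
        for cls, pc in sc.percent_by_class.items():
            row[f"percent_{cls}"] = pc
        acc_rows.append(row)
    accuracy = pd.DataFrame(acc_rows)
    accuracy = accuracy[~accuracy.excluded].reset_index(drop=True)

    summary_rows = []
    for cond in config.conditions:
        for task in TASKS:
            vals = accuracy.query("condition == @cond and task == @task")[
                "percent_correct"
            ]
            summary_rows.append(
                {
                    "condition": cond,
                    "task": task,
                    "tp_class": "all",
                    "mean": vals.mean(),
                    "sd": vals.std(ddof=1),
                    "n": len(vals),
                }
            )
    if "mixed" in config.conditions:
        for task in TASKS:
            sub = accuracy.query("condition == 'mixed' and task == @task")
            for cls in ("high", "low"):
                col = f"percent_{cls}"
                if col in sub:
                    summary_rows.append(
                        {
                            "condition": "mixed",
                            "task": task,
                            "tp_class": cls,
                            "mean": sub[col].mean(),
                            "sd": sub[col].std(ddof=1),
                            "n": len(sub),
                        }
                    )
    behavioral_summary = pd.DataFrame(summary_rows)
    _log("scoring", t0, rows=len(accuracy))

    # inference
    t0 = time.perf_counter()
    chance_rows = []
    for _, srow in behavioral_summary.iterrows():
        res = one_sample_t(mean=srow["mean"], sd=srow["sd"], n=int(srow["n"]))
        chance_rows.append(
            {
                "condition": srow["condition"],
                "task": srow["task"],
                "tp_class": srow["tp_class"],
                "t": res.t,
                "df": res.df,
                "p": res.p,
            }
        )
    chance_tests = pd.DataFrame(chance_rows)

    effect_frames = []
    if len(config.conditions) > 1:
        res = mixed_rm_anova(
            accuracy,
            dv="percent_correct",
            subject="participant",
            between="condition",
            within=["task"],
        )
        tab = anova_table(res)
        tab.insert(0, "analysis", "stream_x_task")
        effect_frames.append(tab)
    if "mixed" in config.conditions:
        sub = accuracy.query("condition == 'mixed'")
        long = pd.melt(
            sub[["participant", "task", "percent_high", "percent_low"]],
            id_vars=["participant", "task"],
            value_vars=["percent_high", "percent_low"],
            var_name="tp_class",
            value_name="percent_correct",
        )
        long["tp_class"] = long["tp_class"].str.removeprefix("percent_")
        res = mixed_rm_anova(
            long,
            dv="percent_correct",
            subject="participant",
            within=["tp_class", "task"],
        )
        tab = anova_table(res)
        tab.insert(0, "analysis", "mixed_wordtype_x_task")
        effect_frames.append(tab)
    effects = pd.concat(effect_frames, ignore_index=True)
    _log("inference", t0, effects=len(effects))

    # ERP stage (scaled by n_eeg_per_group)
    erp_peaks = None
    if config.n_eeg_per_group > 0:
        t0 = time.perf_counter()
        ch_names = CHANNELS_66 if config.eeg_montage == "full" else REDUCED_MONTAGE
        effects_params = default_erp_effects(
            noise_rms_uv=config.noise_rms_uv, artifact_rate=config.artifact_rate
        )
        peak_frames = []
        for ci, cond in enumerate(config.conditions):
            for k in range(config.n_eeg_per_group):
                try:
                    rec = simulate_eeg(
                        streams[cond],
                        effects_params,
                        seed=config.seeds["eeg"] + 100 * ci + k,
                        ch_names=ch_names,
                    )
                    eps = epoch(preprocess(rec))
                    eps, excluded = reject(eps)
                    if excluded:
                        continue
                    evs = evoked(eps, ("condition", "half"))
                    tab = peak_table(evs, COMPONENTS)
                    tab.insert(0, "participant", f"{cond}_{k}")
                    peak_frames.append(tab)
                except DesignError as exc:
                    raise DesignError(
                        f"stage=erp condition={cond} participant={k} "
                        f"seed={config.seeds['eeg'] + 100 * ci + k}: {exc}"
                    ) from exc
        erp_peaks = pd.concat(peak_frames, ignore_index=True)
        _log("erp", t0, recordings=len(peak_frames))

    manifest = {
        "package_version": __version__,
        "config": {
            **{k: v for k, v in asdict(config).items() if k != "output_dir"},
            "conditions": list(config.conditions),
        },
        "n_participants": int(pid),
        "n_word_tokens": {c: len(s.word_tokens) for c, s in streams.items()},
        "afc_trials_per_list": 16,
        "tasks": list(TASKS),
    }

    bundle = RunBundle(
        config,
        streams,
        words_by_cond,
        foils_by_cond,
        stream_reports,
        responses,
        accuracy,
        behavioral_summary,
        effects,
        chance_tests,
        erp_peaks,
        manifest,
    )
    if config.output_dir:
        write_bundle(bundle, config.output_dir)
    return bundle


def write_bundle(bundle: RunBundle, out_dir: str) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.stream_reports.to_csv(out / "stream_report.csv", index=False)
    bundle.accuracy.to_csv(out / "accuracy.csv", index=False)
    bundle.behavioral_summary.to_csv(out / "behavioral_summary.csv", index=False)
    bundle.chance_tests.to_csv(out / "chance_tests.csv", index=False)
    bundle.effects.to_csv(out / "effects.csv", index=False)
    if bundle.erp_peaks is not None:
        bundle.erp_peaks.to_csv(out / "erp_peaks.csv", index=False)
    for cond, seq in bundle.streams.items():
        write_events_tsv(seq, str(out / f"events_{cond}.tsv"))
    with open(out / "manifest.json", "w") as fh:
        json.dump(bundle.manifest, fh, indent=2, sort_keys=True)


def verify_claims(bundle: RunBundle) -> pd.DataFrame:
    """Assert the design statistics of a completed bundle; per-claim pass/fail."""
    rows = []

    def check(name: str, value, passed: bool) -> None:
        rows.append({"claim": name, "value": value, "passed": bool(passed)})

    for cond, seq in bundle.streams.items():
        words = bundle.words[cond]
        theo_within = theoretical_within_tp(words)
        emp_within = empirical_within_tp(seq)
        expected = {"unmixed_high": 1.0, "unmixed_low": 1 / 3}.get(cond)
        if expected is not None:
            vals = list(theo_within.values())
            check(
                f"{cond}: within-word TP = {expected:.2f}",
                round(float(np.mean(vals)), 4),
                all(abs(v - expected) < 1e-12 for v in vals),
            )
            check(
                f"{cond}: empirical within-word TP near design",
                round(
                    max(
                        abs(emp_within.get(k, 0.0) - theo_within[k])
                        for k in theo_within
                    ),
                    4,
                ),
                all(
                    abs(emp_within.get(k, 0.0) - theo_within[k]) <= 0.02
                    for k in theo_within
                ),
            )
        theo = theoretical_tp(words, cond)
        boundary_expected = 0.5 if cond == "unmixed_low" else 1 / 3
        probs = [p for succ in theo.boundary_successors.values() for p in succ.values()]
        check(
            f"{cond}: boundary successor probability = {boundary_expected:.2f}",
            round(float(np.mean(probs)), 4),
            all(abs(p - boundary_expected) < 1e-12 for p in probs),
        )
        # word-boundary adjacency also holds empirically (no illegal successions)
        emp_bound = empirical_tp(seq).boundary_successors
        illegal = [
            (w, v)
            for w, succ in emp_bound.items()
            for v in succ
            if v not in theo.boundary_successors.get(w, {})
        ]
        check(f"{cond}: no illegal word successions", len(illegal), not illegal)
        check(
            f"{cond}: stream duration 4.2 min",
            seq.total_duration_ms / 60000.0,
            abs(seq.total_duration_ms / 60000.0 - 4.2) < 1e-9,
        )
        check(
            f"{cond}: 240 word / 720 syllable tokens",
            (len(seq.word_tokens), len(seq.syllable_tokens)),
            len(seq.word_tokens) == 240 and len(seq.syllable_tokens) == 720,
        )
        n_chirps = sum(t.chirp for t in seq.syllable_tokens)
        per_pos = [
            sum(t.chirp for t in seq.syllable_tokens if t.position == p)
            for p in (1, 2, 3)
        ]
        check(
            f"{cond}: 72 chirps balanced over positions",
            (n_chirps, tuple(per_pos)),
            n_chirps == 72 and max(per_pos) - min(per_pos) <= 1,
        )
        if cond in ("unmixed_high", "mixed"):
            emp = empirical_tp(seq)
            tps = [
                v
                for foil in bundle.foils[cond]
                for v in foil_tp(foil, emp).values()
            ]
            check(f"{cond}: foil pair TPs all 0", max(tps), max(tps) == 0.0)

    if set(CONDITIONS) <= set(bundle.streams):
        h = {
            cond: entropy(theoretical_tp(bundle.words[cond], cond)).value
            for cond in CONDITIONS
        }
        check(
            "entropy ordering low > mixed > high",
            {k: round(v, 3) for k, v in h.items()},
            h["unmixed_low"] > h["mixed"] > h["unmixed_high"],
        )
    return pd.DataFrame(rows)
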