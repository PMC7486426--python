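"""Trial-table and config file formats, plus end-to-end orchestration.

Tables are RFC-4180 CSV with a required header; configs are YAML; results
are JSON.  ``run_experiment`` chains the synthetic cohort generator and
the full statistical pipeline and writes a manifest (seeds, config hash,
package version) sufficient to reproduce any run byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import CohortConfig, generate_cohort
from .emotions import Expression, Orientation, SelfReportEmotion, express
from .game import Move, Outcome
from .zd import MemoryOneStrategy
from . import stats

log = logging.getLogger("coopsignal")

__all__ = [
    "TRIAL_COLUMNS",
    "SchemaError",
    "read_trial_table",
    "write_trial_table",
    "read_cohort_config",
    "write_cohort_config",
    "read_strategy",
    "write_strategy",
    "RunConfig",
    "run_experiment",
]

TRIAL_COLUMNS = [
    "participant_id",
    "strategy",
    "emotion",
    "round",
    "participant_move",
    "counterpart_move",
    "outcome",
    "counterpart_expression",
    "self_report",
    "expectation_rating",
]

_ENUMS = {
    "strategy": {"extortion", "generosity"},
    "emotion": {o.value for o in Orientation},
    "participant_move": {m.value for m in Move},
    "counterpart_move": {m.value for m in Move},
    "outcome": {o.value for o in Outcome},
    "counterpart_expression": {e.value for e in Expression},
    "self_report": {e.value for e in SelfReportEmotion},
}


class SchemaError(ValueError):
    """A trial table violating the documented schema; carries a row number."""


def read_trial_table(path) -> pd.DataFrame:
    """Read and validate a trial-table CSV.

    Checks the header, the enum columns, the round range, and that each
    row's outcome is consistent with the two moves (participant move
    first).  Raises :class:`SchemaError` naming the first offending row.
    """
    try:
        df = pd.read_csv(path, dtype={"participant_id": str})
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file") from exc
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        raise SchemaError(f"{path}: no data rows")
    for col, allowed in _ENUMS.items():
        bad = ~df[col].isin(allowed)
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise SchemaError(
                f"{path}: row {row + 2}: invalid {col} value {df[col].iloc[row]!r}"
            )
    rounds = pd.to_numeric(df["round"], errors="coerce")
    bad = rounds.isna() | (rounds < 1) | (rounds != rounds.astype(int))
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise SchemaError(f"{path}: row {row + 2}: invalid round {df['round'].iloc[row]!r}")
    df["round"] = rounds.astype(int)
    expected = df["participant_move"].str.cat(df["counterpart_move"])
    bad = expected != df["outcome"]
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise SchemaError(
            f"{path}: row {row + 2}: outcome {df['outcome'].iloc[row]!r} does not "
            f"match moves {expected.iloc[row]!r}"
        )
    df["expectation_rating"] = pd.to_numeric(df["expectation_rating"])
    return df[TRIAL_COLUMNS]


def write_trial_table(df: pd.DataFrame, path) -> None:
    df[TRIAL_COLUMNS].to_csv(path, index=False)


def read_cohort_config(path) -> CohortConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: expected a mapping")
    doc.pop("schema_version", None)
    return CohortConfig.from_dict(doc)


def write_cohort_config(config: CohortConfig, path) -> None:
    doc = {"schema_version": 1, **config.to_dict()}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_strategy_spec(path) -> dict:
    """Raw strategy entry: {'p': [4 values, None allowed], 'initial', 'name'}.

    ``None`` entries mark probabilities to be pinned by ZD completion.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    p = [doc[k] for k in ("p_CC", "p_CD", "p_DC", "p_DD")]
    return {
        "p": p,
        "initial": Move(doc.get("initial_move", "C")),
        "name": doc.get("name", ""),
    }


def read_strategy(path) -> MemoryOneStrategy:
    """Read a complete strategy config: name, p_CC..p_DD, initial_move."""
    spec = read_strategy_spec(path)
    if any(v is None for v in spec["p"]):
        raise ValueError(f"{path}: incomplete strategy (null entries); use ZD completion")
    return MemoryOneStrategy.from_decimals(spec["p"], initial=spec["initial"], name=spec["name"])


def write_strategy(s: MemoryOneStrategy, path) -> None:
    doc = {
        "name": s.name,
        "p_CC": float(s.p[0]),
        "p_CD": float(s.p[1]),
        "p_DC": float(s.p[2]),
        "p_DD": float(s.p[3]),
        "initial_move": s.initial.value,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


@dataclasses.dataclass
class RunConfig:
    """Settings for a full simulate-then-analyze run."""

    cohort: CohortConfig = dataclasses.field(default_factory=CohortConfig)
    n_boot: int = 5000
    analysis_seed: int = 0
    contrast_weights: dict | None = None
    contrast_df_policy: str | int = "omnibus"
    out_dir: str = "coopsignal_run"

    def resolved(self) -> "RunConfig":
        """Make every seed explicit (auto-seeds are drawn once and logged)."""
        cfg = self
        if cfg.cohort.seed is None:
            seed = int(np.random.SeedSequence().entropy % (2**31))
            log.info("auto-generated cohort seed %d", seed)
            cfg = dataclasses.replace(cfg, cohort=dataclasses.replace(cfg.cohort, seed=seed))
        return cfg


def _config_hash(cfg: RunConfig) -> str:
    doc = {
        "cohort": cfg.cohort.to_dict(),
        "n_boot": cfg.n_boot,
        "analysis_seed": cfg.analysis_seed,
        "contrast_weights": {"|".join(k): v for k, v in (cfg.contrast_weights or {}).items()},
        "contrast_df_policy": cfg.contrast_df_policy,
    }
    return hashlib.sha256(json.dumps(doc, sort_keys=True).encode()).hexdigest()[:16]


def analyze_trials(
    trials: pd.DataFrame,
    n_boot: int = 5000,
    seed: int = 0,
    contrast_weights: dict | None = None,
    contrast_df_policy: str | int = "omnibus",
) -> dict:
    """Run the full statistical pipeline on a trial table.

    Returns a dict with the five analysis blocks: factorial ANOVAs on
    cooperation rate / joy / expectation, the planned synergistic
    contrast, per-strategy t tests of the emotion effect, the round x
    strategy x emotion mixed ANOVA, and the two multiple mediations
    (strategy and emotion effects on cooperation rate, mediated by
    expectation and the four self-reported emotions).
    """
    summary = stats.participant_summary(trials)
    mediators = ["expectation", "report_joy", "report_sadness", "report_regret", "report_anger"]

    results: dict = {"n_participants": int(len(summary))}
    anovas = {}
    for dv, label in (("coop_rate", "cooperation"), ("report_joy", "joy"), ("expectation", "expectation")):
        res = stats.anova_two_way(summary, dv, "strategy", "emotion")
        anovas[label] = {
            "table": res.table.to_dict(orient="records"),
            "posthoc": res.posthoc.to_dict(orient="records"),
        }
    results["anova"] = anovas

    con = stats.planned_contrast(
        summary, "coop_rate", weights=contrast_weights, df_policy=contrast_df_policy
    )
    results["planned_contrast"] = {
        "estimate": con.estimate,
        "se": con.se,
        "t": con.t,
        "df": con.df,
        "p": con.p,
        "weights": {"|".join(k): v for k, v in con.weights.items()},
    }

    ttests = {}
    for strat in ("generosity", "extortion"):
        sub = summary[summary["strategy"] == strat]
        res_t = stats.ttest_ind(
            sub.loc[sub["emotion"] == "cooperative", "coop_rate"],
            sub.loc[sub["emotion"] == "competitive", "coop_rate"],
        )
        ttests[strat] = {"t": res_t.t, "df": res_t.df, "p": res_t.p, "r": res_t.r}
    results["emotion_ttests"] = ttests

    trials = trials.copy()
    trials["cooperated"] = (trials["participant_move"] == "C").astype(float)
    mx = stats.mixed_anova(
        trials, "cooperated", within="round", subject="participant_id",
        between=["strategy", "emotion"],
    )
    results["mixed_anova"] = {
        "between": mx.between.to_dict(orient="records"),
        "within": mx.within.to_dict(orient="records"),
        "eps_gg": mx.eps_gg,
        "eps_hf": mx.eps_hf,
    }

    mediations = {}
    for effect, col, level1 in (("strategy", "strategy", "extortion"), ("emotion", "emotion", "competitive")):
        iv = (summary[col] == level1).astype(float)
        med = stats.multiple_mediation(
            iv, summary[mediators], summary["coop_rate"], n_boot=n_boot, seed=seed
        )
        mediations[effect] = {
            "coding": {level1: 1},
            "paths": med.paths.to_dict(orient="records"),
            "total": med.total,
            "direct": med.direct,
            "total_ci": list(med.total_ci),
            "direct_ci": list(med.direct_ci),
            "n_boot": med.n_boot,
            "seed": med.seed,
        }
    results["mediation"] = mediations
    return results


def run_experiment(config: RunConfig) -> dict:
    """Generate a cohort, run all analyses, and write the report bundle.

    Writes trials.csv, post_task.csv, results.json, and manifest.json into
    ``config.out_dir``.  Idempotent for fixed seeds.
    """
    cfg = config.resolved()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    log.info("generating cohort (seed=%s)", cfg.cohort.seed)
    trials, post = generate_cohort(cfg.cohort)
    write_trial_table(trials, out / "trials.csv")
    post.to_csv(out / "post_task.csv", index=False)

    log.info("running analyses (n_boot=%d, seed=%d)", cfg.n_boot, cfg.analysis_seed)
    results = analyze_trials(
        trials,
        n_boot=cfg.n_boot,
        seed=cfg.analysis_seed,
        contrast_weights=cfg.contrast_weights,
        contrast_df_policy=cfg.contrast_df_policy,
    )
    with open(out / "results.json", "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True)

    manifest = {
        "package": "coopsignal",
        "version": __version__,
        "config_hash": _config_hash(cfg),
        "cohort_config": cfg.cohort.to_dict(),
        "n_boot": cfg.n_boot,
        "analysis_seed": cfg.analysis_seed,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return results
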