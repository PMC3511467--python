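"""CSV schemas and run configuration.

Trials travel as UTF-8 CSV with header
``subject_id, amount_ss, amount_ll, delay_days, choice`` — amounts in
euros, delays in float days (fractional days like 0.25 are valid), choices
as the strings SS/LL rather than 0/1 to prevent silent polarity bugs.
Validation errors name the offending row.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence

import pandas as pd
import yaml

from .likelihood import TrialRecord

__all__ = ["RunConfig", "read_trials", "write_trials",
           "read_score_table", "TrialParseError"]

TRIAL_COLUMNS = ["subject_id", "amount_ss", "amount_ll", "delay_days", "choice"]


class TrialParseError(ValueError):
    pass


@dataclass
class RunConfig:
    """Serializable settings for a pipeline run; echoed into the output dir."""

    models: List[str] = field(default_factory=lambda: ["H", "E", "GM", "R", "CS"])
    score_kind: str = "AIC"
    n_starts: int = 20
    seed: int = 0
    bms_mc_samples: int = 1_000_000
    hessian_step: float = 1e-3
    rescale_cs: bool = False
    task: str = "adaptive"
    preset: str = "dataset2"
    n_agents: int = 40
    beta_median: float | None = None
    output_dir: str = "out"

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def read_trials(path) -> Dict[str, List[TrialRecord]]:
    """Load and validate a trials CSV into subject -> TrialRecord lists."""
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise TrialParseError(f"{path}: missing column(s) {missing}")
    dataset: Dict[str, List[TrialRecord]] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header=1
        try:
            rec = TrialRecord(
                subject_id=str(row.subject_id),
                amount_ss=float(row.amount_ss),
                amount_ll=float(row.amount_ll),
                delay_ll=float(row.delay_days),
                choice=str(row.choice),
            )
        except (TypeError, ValueError) as err:
            raise TrialParseError(f"{path}: row {i}: {err}") from err
        dataset.setdefault(rec.subject_id, []).append(rec)
    return dataset


def write_trials(dataset: Dict[str, Sequence[TrialRecord]], path) -> None:
    rows = [
        {"subject_id": t.subject_id, "amount_ss": t.amount_ss,
         "amount_ll": t.amount_ll, "delay_days": t.delay_ll,
         "choice": t.choice}
        for trials in dataset.values() for t in trials
    ]
    pd.DataFrame(rows, columns=TRIAL_COLUMNS).to_csv(path, index=False)


def read_score_table(path):
    """Wide (subject x model) score CSV -> ScoreTable."""
    from .selection import ScoreTable

    df = pd.read_csv(path, index_col=0)
    return ScoreTable(df, score_kind="AIC")
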