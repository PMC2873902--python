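"""On-disk formats and run configuration.

Everything is plain text: trials, responses, salience tables and fit
results as tab-delimited files with headers; stimuli as JSON; bias maps
and feature maps as whitespace arrays with a JSON metadata comment line;
images as 8-bit gray-scale PNG; run configuration as YAML.  All writers
round-trip losslessly through their readers.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .stimulus import Bubble, Fixation, ScreenGeometry, Stimulus, Trial

TRIAL_COLUMNS = ["participant", "stimulus", "fix_index", "x_deg", "y_deg", "response"]
RESPONSE_COLUMNS = ["participant", "stimulus", "response"]


class SchemaError(ValueError):
    pass


def _check_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")


# ---------------------------------------------------------------------------
# trials
# ---------------------------------------------------------------------------


def save_trials(trials: list[Trial], path) -> None:
    rows = []
    for t in trials:
        for f in t.fixations:
            rows.append(
                (t.participant_id, t.stimulus_id, f.order_index, f.x_deg, f.y_deg, t.response)
            )
    pd.DataFrame(rows, columns=TRIAL_COLUMNS).to_csv(path, sep="\t", index=False)


def load_trials(path) -> list[Trial]:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"participant": str, "stimulus": str},
        float_precision="round_trip",
    )
    _check_columns(df, TRIAL_COLUMNS, path)
    df["response"] = df["response"].fillna("")
    trials = []
    for (pid, sid, resp), grp in df.groupby(
        ["participant", "stimulus", "response"], sort=False
    ):
        grp = grp.sort_values("fix_index")
        fixes = tuple(
            Fixation(float(r.x_deg), float(r.y_deg), int(r.fix_index))
            for r in grp.itertuples()
        )
        trials.append(Trial(str(pid), str(sid), fixes, str(resp)))
    return trials


def save_responses(responses: pd.DataFrame, path) -> None:
    out = responses.rename(
        columns={"participant_id": "participant", "stimulus_id": "stimulus"}
    )
    out[RESPONSE_COLUMNS].to_csv(path, sep="\t", index=False)


def load_responses(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _check_columns(df, RESPONSE_COLUMNS, path)
    return df.rename(
        columns={"participant": "participant_id", "stimulus": "stimulus_id"}
    )


# ---------------------------------------------------------------------------
# stimuli
# ---------------------------------------------------------------------------


def save_stimuli(stimuli: list[Stimulus], path) -> None:
    payload = [
        {
            "stimulus_id": s.stimulus_id,
            "task": s.task,
            "condition": s.condition,
            "bubbles": [dataclasses.asdict(b) for b in s.bubbles],
        }
        for s in stimuli
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def load_stimuli(path) -> list[Stimulus]:
    payload = json.loads(Path(path).read_text())
    out = []
    for d in payload:
        bubbles = tuple(Bubble(**b) for b in d["bubbles"])
        out.append(Stimulus(d["stimulus_id"], d["task"], bubbles, d["condition"]))
    return out


# ---------------------------------------------------------------------------
# salience / fit tables
# ---------------------------------------------------------------------------


def save_salience(series: pd.Series, path, name: str = "salience") -> None:
    pd.DataFrame({"bubble_id": series.index, name: series.values}).to_csv(
        path, sep="\t", index=False
    )


def load_salience(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype={"bubble_id": str})
    _check_columns(df, ["bubble_id"], path)
    value_col = [c for c in df.columns if c != "bubble_id"][0]
    return pd.Series(
        df[value_col].to_numpy(),
        index=pd.Index(df["bubble_id"], name="bubble_id"),
        name=value_col,
    )


def save_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def load_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# arrays with geometry header, images
# ---------------------------------------------------------------------------


def save_map(grid: np.ndarray, path, meta: dict | None = None) -> None:
    header = json.dumps({"shape": list(grid.shape), **(meta or {})})
    np.savetxt(path, grid, header=header)


def load_map(path) -> tuple[np.ndarray, dict]:
    with open(path) as fh:
        first = fh.readline()
    meta = json.loads(first.lstrip("# ").strip())
    grid = np.loadtxt(path)
    return grid.reshape(meta["shape"]), meta


def save_image(img: np.ndarray, path) -> None:
    """Write a [0, 1] gray-scale array as 8-bit PNG/PGM."""
    arr = np.clip(np.asarray(img, float), 0.0, 1.0)
    Image.fromarray((arr * 255).round().astype(np.uint8), mode="L").save(path)


def load_image(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("L"), dtype=float) / 255.0


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Seed, geometry, design and path settings of one pipeline run."""

    seed: int = 0
    task: str = "gender"
    n_bubbles: int = 94
    n_stimuli: int = 300
    n_participants: int = 75
    trials_per_participant: int = 280
    mean_fixations: float = 6.2
    landing_scatter_sd_deg: float = 0.45
    corrective_approach_deg: float = 0.16
    weights: list = field(default_factory=lambda: [0.3, 0.5, 0.7])
    log_noise_sd: float = 0.3
    concentration: float = 0.5
    grid_step_deg: float = 0.25
    baseline_participants: int = 27
    baseline_trials_each: int = 40
    prob_floor: float = 1e-6
    out_dir: str = "run"

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"{path}: unknown config key(s) {sorted(unknown)}")
        return cls(**data)

    def geometry(self) -> ScreenGeometry:
        return ScreenGeometry()

    def config_hash(self) -> str:
        import hashlib

        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
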