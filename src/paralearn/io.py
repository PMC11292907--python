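"""CSV/JSON/YAML round-tripping and run configuration.

File conventions: UTF-8 comma-separated CSV with a header row and "."
decimal; trial indices are 0-based in every table. Long trial tables carry
one row per participant-trial:

* blocking: participant_id, task="blocking", trial, phase, cue1, cue2
  (empty for single-cue trials), outcome (+1/-1), response ([-1, 1]),
  category_id, gives_feedback
* prl: participant_id, task="prl", trial, block, choice, outcome
  (+100/-50)

Fits and model-comparison tables are serialized to JSON. Every pipeline
run can emit a provenance record (config hash, seeds, package version).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import SyntheticParticipant
from .tasks import BlockingTrial

__all__ = [
    "RunConfig",
    "blocking_table",
    "prl_table",
    "read_blocking_table",
    "validate_blocking_table",
    "truth_records",
    "write_json",
    "read_json",
    "provenance",
]

BLOCKING_COLUMNS = ["participant_id", "task", "trial", "phase", "cue1", "cue2",
                    "outcome", "response", "category_id", "gives_feedback"]
PRL_COLUMNS = ["participant_id", "task", "trial", "block", "choice", "outcome"]


@dataclass
class RunConfig:
    """Schema-checked knobs for a pipeline run, loadable from YAML."""

    seed: int = 0
    n_participants: int = 30
    variants: list[str] = field(default_factory=lambda: ["RW1", "RW2", "RW3", "RW4", "RW5"])
    n_starts: int = 25
    hgf_n_starts: int = 6
    hgf_per_block: bool = True
    bms_alpha0: float = 1.0
    bms_n_mc: int = 100_000
    blocking_noise_sd: float = 0.2
    output_dir: str = "paralearn_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        from .blocking import VARIANTS

        if self.seed < 0 or self.n_participants < 1:
            raise ValueError("seed must be >= 0 and n_participants >= 1")
        bad = [v for v in self.variants if v not in VARIANTS]
        if bad:
            raise ValueError(f"unknown model variant(s): {bad}")
        if self.n_starts < 1 or self.hgf_n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if self.blocking_noise_sd < 0:
            raise ValueError("blocking_noise_sd must be >= 0")

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def blocking_table(participants: list[SyntheticParticipant]) -> pd.DataFrame:
    rows = []
    for p in participants:
        if p.blocking_responses is None:
            raise ValueError(f"{p.id}: no blocking responses simulated")
        for t, resp in zip(p.blocking_trials, p.blocking_responses):
            rows.append({
                "participant_id": p.id,
                "task": "blocking",
                "trial": t.index,
                "phase": t.phase,
                "cue1": t.cues[0],
                "cue2": t.cues[1] if len(t.cues) == 2 else "",
                "outcome": t.outcome,
                "response": float(resp),
                "category_id": t.category_id,
                "gives_feedback": t.gives_feedback,
            })
    return pd.DataFrame(rows, columns=BLOCKING_COLUMNS)


def prl_table(participants: list[SyntheticParticipant]) -> pd.DataFrame:
    rows = []
    for p in participants:
        if p.prl is None or not p.prl.completed:
            raise ValueError(f"{p.id}: no completed PRL session")
        per = p.prl.trials_per_block
        for t in range(p.prl.n_trials):
            rows.append({
                "participant_id": p.id,
                "task": "prl",
                "trial": t,
                "block": t // per,
                "choice": int(p.prl.choices[t]),
                "outcome": int(p.prl.outcomes[t]),
            })
    return pd.DataFrame(rows, columns=PRL_COLUMNS)


def validate_blocking_table(df: pd.DataFrame) -> None:
    """Raise with the offending row number on a malformed table."""
    missing = set(BLOCKING_COLUMNS[:8]) - set(df.columns)
    if missing:
        raise ValueError(f"blocking table missing columns: {sorted(missing)}")
    resp = pd.to_numeric(df["response"], errors="coerce")
    bad = df.index[resp.isna() | (resp.abs() > 1.0)]
    if len(bad):
        raise ValueError(
            f"row {int(bad[0])}: response {df.loc[bad[0], 'response']!r} "
            f"is not a number in [-1, 1]")
    bad = df.index[~df["outcome"].isin([1, -1])]
    if len(bad):
        raise ValueError(f"row {int(bad[0])}: outcome must be +1 or -1")


def read_blocking_table(path: str | Path) -> dict[str, tuple[list[BlockingTrial], np.ndarray]]:
    """Read a long blocking table back into per-participant trial streams."""
    df = pd.read_csv(path, keep_default_na=False)
    validate_blocking_table(df)
    out: dict[str, tuple[list[BlockingTrial], np.ndarray]] = {}
    for pid, g in df.groupby("participant_id", sort=False):
        g = g.sort_values("trial")
        trials = []
        prev_phase = None
        seen: dict[str, int] = {}
        for _, row in g.iterrows():
            cues = (row["cue1"],) if row["cue2"] == "" else (row["cue1"], row["cue2"])
            cid = row.get("category_id", "+".join(cues))
            seen[cid] = seen.get(cid, 0) + 1
            phase = int(row["phase"])
            fb = row["gives_feedback"] if "gives_feedback" in row else True
            trials.append(BlockingTrial(
                index=int(row["trial"]),
                phase=phase,
                category_id=cid,
                cues=tuple(sorted(cues)),
                outcome=int(row["outcome"]),
                is_first_of_phase=(prev_phase is not None and phase != prev_phase),
                gives_feedback=bool(fb) if not isinstance(fb, str) else fb == "True",
                presentation=seen[cid],
            ))
            prev_phase = phase
        out[str(pid)] = (trials, g["response"].to_numpy(dtype=float))
    return out


def truth_records(participants: list[SyntheticParticipant]) -> dict:
    """Ground-truth parameters keyed by participant id (sidecar JSON)."""
    return {
        p.id: {
            "phenotype": p.phenotype,
            "high_paranoia": p.high_paranoia,
            "high_pdic": p.high_pdic,
            "rw": {k: getattr(p.rw, k) for k in ("alpha", "gamma", "lam", "eta")},
            "hgf": {k: getattr(p.hgf, k) for k in (
                "mu0_2", "sigma0_2", "mu0_3", "sigma0_3",
                "kappa", "omega2", "omega3", "beta")},
        }
        for p in participants
    }


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True))


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def provenance(config: RunConfig) -> dict:
    return {
        "package": "paralearn",
        "version": __version__,
        "config_hash": config.hash(),
        "config": asdict(config),
        "seed": config.seed,
    }
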