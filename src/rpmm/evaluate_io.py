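"""Evaluation metrics and plain-text I/O.

Precision and recall follow the inlier-preservation convention: precision is
the fraction of preserved correspondences that are true inliers, recall the
fraction of true inliers that were preserved.  Component identity is ignored
by the headline numbers (any positive label counts as "preserved") but
component-resolved counts are kept as diagnostics.

Point and pair tables are TSV/CSV with optional header and '#' comments;
reports are JSON.
"""

from __future__ import annotations

import dataclasses
import json
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "EvalReport",
    "precision_recall",
    "registration_recall_curve",
    "read_points",
    "write_points",
    "read_pairs",
    "write_report",
]

_DELIMS = re.compile(r"[,\t ]+")


@dataclass
class EvalReport:
    """Inlier-level precision/recall with supporting counts."""

    precision: float | None
    recall: float
    counts: tuple[int, int, int]          # (preserved, preserved_true, total_true)
    per_component: dict

    def to_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "preserved": self.counts[0],
            "preserved_true": self.counts[1],
            "total_true": self.counts[2],
            "per_component": self.per_component,
        }


def precision_recall(pred_labels: np.ndarray, true_labels: np.ndarray) -> EvalReport:
    """Inlier precision and recall of a predicted labeling.

    A pair is preserved when its predicted label is positive; correctness is
    judged on inlier-vs-outlier only, not component identity.  Precision is
    None when nothing was preserved; recall is 0 when there are no true
    inliers preserved.
    """
    pred = np.asarray(pred_labels, dtype=int).ravel()
    true = np.asarray(true_labels, dtype=int).ravel()
    if pred.shape != true.shape:
        raise ValueError(f"label lengths differ: {pred.size} vs {true.size}")
    preserved = int(np.sum(pred > 0))
    preserved_true = int(np.sum((pred > 0) & (true > 0)))
    total_true = int(np.sum(true > 0))
    precision = preserved_true / preserved if preserved > 0 else None
    recall = preserved_true / total_true if total_true > 0 else 0.0
    per_component = {
        int(l): {
            "preserved": int(np.sum(pred == l)),
            "preserved_true": int(np.sum((pred == l) & (true > 0))),
        }
        for l in np.unique(pred[pred > 0])
    }
    return EvalReport(precision=precision, recall=recall,
                      counts=(preserved, preserved_true, total_true),
                      per_component=per_component)


def registration_recall_curve(
    warped: np.ndarray,
    target: np.ndarray,
    pairing: np.ndarray,
    thresholds,
) -> list[tuple[float, float]]:
    """Recall vs distance threshold for a registered point set.

    For each threshold t, recall(t) is the fraction of ground-truth pairs
    (i, j) whose post-registration distance ||warped_i - target_j|| is at
    most t.  Monotone non-decreasing in t.
    """
    warped = np.atleast_2d(np.asarray(warped, dtype=float))
    target = np.atleast_2d(np.asarray(target, dtype=float))
    pairing = np.asarray(pairing)
    if pairing.size == 0:
        raise ValueError("pairing is empty")
    if pairing.ndim == 1:
        pairs = np.stack([np.arange(pairing.size), pairing], axis=1)
    else:
        pairs = pairing
    d = np.linalg.norm(warped[pairs[:, 0]] - target[pairs[:, 1]], axis=1)
    return [(float(t), float(np.mean(d <= t))) for t in thresholds]


def _parse_table(path) -> np.ndarray:
    rows = []
    width = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cells = [c for c in _DELIMS.split(line) if c]
            try:
                vals = [float(c) for c in cells]
            except ValueError:
                if width is None:
                    # first data-ish line may be a header
                    continue
                raise ValueError(f"{path}: non-numeric cell at line {lineno}") from None
            if width is None:
                width = len(vals)
            elif len(vals) != width:
                raise ValueError(
                    f"{path}: ragged row at line {lineno} "
                    f"({len(vals)} columns, expected {width})"
                )
            rows.append(vals)
    if not rows:
        raise ValueError(f"{path}: no data rows")
    return np.asarray(rows, dtype=float)


def read_points(path) -> np.ndarray:
    """Read an N x D point table (TSV/CSV, optional header, '#' comments)."""
    arr = _parse_table(path)
    if arr.shape[1] not in (2, 3):
        raise ValueError(f"{path}: expected 2 or 3 coordinate columns, got {arr.shape[1]}")
    return arr


def write_points(points: np.ndarray, path) -> None:
    """Write a point table as TSV with full round-trip precision."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    np.savetxt(path, pts, delimiter="\t", fmt="%.17g")


def read_pairs(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a correspondence table: 2D columns, x-coordinates then y-coordinates."""
    arr = _parse_table(path)
    if arr.shape[1] not in (4, 6):
        raise ValueError(
            f"{path}: expected 4 or 6 columns (x then y coordinates), got {arr.shape[1]}"
        )
    d = arr.shape[1] // 2
    return arr[:, :d], arr[:, d:]


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    return obj


def write_report(result, path, extra: dict | None = None) -> None:
    """Serialize a MatchResult to JSON: labels, mixture summary, config echo."""
    from . import __version__

    state = result.state
    payload = {
        "labels": result.labels.tolist(),
        "n_inliers": result.n_inliers,
        "n_components": state.L,
        "gammas": state.gammas.tolist(),
        "sigma2": float(state.sigma2),
        "sigma_original_units": result.sigma_original,
        "energy_trace": [float(e) for e in state.energy_trace],
        "converged": bool(result.converged),
        "n_iter": int(result.n_iter),
        "config": _jsonify(dataclasses.asdict(result.config)),
        "seed": int(result.config.seed),
        "version": __version__,
    }
    if extra:
        payload.update(_jsonify(extra))
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
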