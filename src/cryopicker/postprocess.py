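"""From raw slot predictions to final picked coordinates and files.

Slots whose most probable class is ∅ are dropped; the survivors are
de-normalized from the padded batch frame back to pixels of the original
micrograph, clipped to its bounds, and filtered by confidence: only picks
whose score reaches the per-micrograph 25th percentile (configurable) are
retained. Retained picks are written as one EMAN-style box file per
micrograph plus a single merged STAR file carrying scores.

No non-maximum suppression is applied by default — the set-prediction
formulation penalizes duplicate slots during training — but an optional
center-distance de-duplication is available for models that still emit
near-coincident picks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .formats_io import StarRecord, write_box_file, write_star
from .model import PredictionSet

__all__ = [
    "ScoredParticle",
    "predictions_to_particles",
    "percentile_filter",
    "deduplicate",
    "export_pick_results",
]


@dataclass
class ScoredParticle:
    """A picked particle in original-micrograph pixel coordinates."""

    micrograph_id: str
    cx: float
    cy: float
    bw: float
    bh: float
    score: float

    def __post_init__(self):
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score {self.score} outside [0, 1]")


def predictions_to_particles(
    pred: PredictionSet,
    micrograph_id: str,
    micrograph_dims: tuple[int, int],
    pad_dims: tuple[int, int] | None = None,
) -> list[ScoredParticle]:
    """Keep non-∅ slots and map their boxes back to pixels.

    ``micrograph_dims`` is the original (H0, W0); ``pad_dims`` the padded
    frame the normalized boxes refer to (defaults to the original). Centers
    are clipped into the original bounds; score = predicted probability of
    the particle class.
    """
    h0, w0 = micrograph_dims
    ph, pw = pad_dims if pad_dims is not None else (h0, w0)
    out = []
    keep = pred.class_probs.argmax(axis=1) == 0  # column 0 = particle
    for box, probs in zip(pred.boxes[keep], pred.class_probs[keep]):
        cx = float(np.clip(box[0] * pw, 0, w0 - 1))
        cy = float(np.clip(box[1] * ph, 0, h0 - 1))
        out.append(
            ScoredParticle(
                micrograph_id=micrograph_id,
                cx=cx,
                cy=cy,
                bw=float(box[2] * pw),
                bh=float(box[3] * ph),
                score=float(probs[0]),
            )
        )
    return out


def percentile_filter(particles, lower_percentile: float = 25.0) -> list[ScoredParticle]:
    """Retain picks whose score is at least the ``lower_percentile``-th
    percentile of the list's scores.

    The threshold is the observed score at the floor of the percentile rank
    (``np.percentile`` with ``method="lower"``), so at least
    ``ceil((1 - q/100) * n)`` picks always survive. Ties at the threshold
    are kept; order is preserved; empty in, empty out.
    """
    if not 0 <= lower_percentile < 100:
        raise ValueError("lower_percentile must lie in [0, 100)")
    particles = list(particles)
    if not particles:
        return []
    scores = np.array([p.score for p in particles])
    threshold = np.percentile(scores, lower_percentile, method="lower")
    return [p for p in particles if p.score >= threshold]


def deduplicate(particles, min_center_distance: float) -> list[ScoredParticle]:
    """Optional greedy de-duplication: keep the higher-scoring pick of any
    pair closer than ``min_center_distance`` px (off by default upstream)."""
    kept: list[ScoredParticle] = []
    for p in sorted(particles, key=lambda q: -q.score):
        if all(
            (p.cx - k.cx) ** 2 + (p.cy - k.cy) ** 2 >= min_center_distance**2 for k in kept
        ):
            kept.append(p)
    kept.sort(key=lambda q: particles.index(q))
    return kept


def export_pick_results(per_micrograph, out_dir, box_size: int) -> dict:
    """Write per-micrograph box files and one merged, scored STAR file.

    ``per_micrograph`` maps micrograph id -> list of retained
    :class:`ScoredParticle`. Returns (and writes as JSON) a count summary.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    star_records = []
    counts = {}
    for mic_id, particles in per_micrograph.items():
        write_box_file(particles, out_dir / f"{mic_id}.box", box_size=box_size)
        counts[mic_id] = len(particles)
        star_records.extend(
            StarRecord(micrograph_id=mic_id, x=p.cx, y=p.cy, score=p.score) for p in particles
        )
    write_star(star_records, out_dir / "particles.star")
    summary = {
        "n_micrographs": len(per_micrograph),
        "n_particles": int(sum(counts.values())),
        "per_micrograph": counts,
        "box_size": int(box_size),
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary
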