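"""Evaluation metrics and the clinical end-product measurements.

The headline accuracy metric is the average Euclidean distance (AED): for
a set of N images, AED = (1/2N) * sum_i (||left error_i|| + ||right
error_i||), i.e. the mean per-side endpoint error in pixels.  The lesion
diameter is the 2-norm of the vector between the located left and right
boundary points.  A cascade run "successfully corrects" an image when its
single-image AED is strictly below the initializer's on that image.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .phantom import Annotation

__all__ = ["aed", "diameter", "correction_rate", "patient_summary",
           "EvaluationReport"]


def _point_pairs(results):
    """Accept LocationResult-likes or bare ((lx,ly),(rx,ry)) pairs."""
    out = []
    for r in results:
        if hasattr(r, "final_points"):
            out.append(r.final_points)
        else:
            left, right = r
            out.append((tuple(left), tuple(right)))
    return out


def aed(results, truths) -> float:
    """Average Euclidean distance in pixels over aligned results/truths."""
    if len(results) != len(truths):
        raise ValueError("results and truths must be aligned")
    if len(results) == 0:
        raise ValueError("need at least one image")
    total = 0.0
    for (left, right), ann in zip(_point_pairs(results), truths):
        lg = np.subtract(left, ann.left_point)
        rg = np.subtract(right, ann.right_point)
        total += float(np.linalg.norm(lg)) + float(np.linalg.norm(rg))
    return total / (2 * len(results))


def diameter(left, right) -> float:
    """Lesion diameter: 2-norm of the left-to-right boundary vector."""
    return float(np.linalg.norm(np.subtract(right, left)))


def correction_rate(init_results, joint_results, truths
                    ) -> tuple[float, int]:
    """Fraction (and count) of images the cascade strictly improves.

    Per image the single-image AED of the joint result is compared with
    the initializer's; ties count as non-corrections.
    """
    if not (len(init_results) == len(joint_results) == len(truths)):
        raise ValueError("all three lists must be aligned")
    if len(truths) == 0:
        raise ValueError("need at least one image")
    successes = 0
    for init_r, joint_r, ann in zip(init_results, joint_results, truths):
        a_init = aed([init_r], [ann])
        a_joint = aed([joint_r], [ann])
        if a_joint < a_init:
            successes += 1
    return successes / len(truths), successes


def patient_summary(diameters) -> tuple[float, float, float]:
    """(max, min, mean) lesion diameter over one patient's frames."""
    d = np.asarray(list(diameters), dtype=np.float64)
    if d.size == 0:
        raise ValueError("patient has no frames")
    return float(d.max()), float(d.min()), float(d.mean())


@dataclass
class EvaluationReport:
    """Aggregated evaluation of a cascade run over one or more patients."""

    per_patient_aed: dict = field(default_factory=dict)
    image_aed: float = float("nan")
    patient_aed: float = float("nan")
    correction_rate: float = float("nan")
    correction_count: int = 0
    n_images: int = 0
    per_frame_diameters: dict = field(default_factory=dict)
    per_patient_diameter: dict = field(default_factory=dict)

    @classmethod
    def build(cls, joint_results, truths, init_results=None,
              patient_ids=None) -> "EvaluationReport":
        """Assemble the report; patient grouping follows ``patient_ids``.

        ``image_aed`` weights every image equally; ``patient_aed``
        averages the per-patient AEDs (the headline number).
        """
        n = len(truths)
        ids = patient_ids or [getattr(r, "patient_id", "") or "all"
                              for r in joint_results]
        rep = cls(n_images=n)
        rep.image_aed = aed(joint_results, truths)
        groups: dict[str, list[int]] = {}
        for i, pid in enumerate(ids):
            groups.setdefault(pid, []).append(i)
        for pid, idx in groups.items():
            rep.per_patient_aed[pid] = aed([joint_results[i] for i in idx],
                                           [truths[i] for i in idx])
            dias = [diameter(*_point_pairs([joint_results[i]])[0])
                    for i in idx]
            rep.per_frame_diameters[pid] = dias
            rep.per_patient_diameter[pid] = patient_summary(dias)
        rep.patient_aed = float(np.mean(list(rep.per_patient_aed.values())))
        if init_results is not None:
            rate, count = correction_rate(init_results, joint_results, truths)
            rep.correction_rate = rate
            rep.correction_count = count
        return rep

    def to_json(self, path) -> None:
        d = {
            "image_aed": self.image_aed,
            "patient_aed": self.patient_aed,
            "per_patient_aed": self.per_patient_aed,
            "correction_rate": self.correction_rate,
            "correction_count": self.correction_count,
            "n_images": self.n_images,
            "per_patient_diameter": {
                k: {"max": v[0], "min": v[1], "mean": v[2]}
                for k, v in self.per_patient_diameter.items()
            },
        }
        Path(path).write_text(json.dumps(d, indent=2))

    def to_csv(self, path) -> None:
        rows = []
        for pid, dias in self.per_frame_diameters.items():
            for k, d in enumerate(dias):
                rows.append({"patient_id": pid, "frame": k, "diameter_px": d,
                             "patient_aed_px": self.per_patient_aed[pid]})
        pd.DataFrame(rows).to_csv(path, index=False)
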