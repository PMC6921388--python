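"""Slice-by-slice driver: pre-processing -> segmentation -> refinement.

``run_pipeline`` is a pure function of its (stack, config) arguments —
repeated runs are bit-identical — and returns one binary Z-disk mask per
slice together with a run report tallying the directional convolutions
(2 per slice), intersection operations (1 per slice), membrane
convolutions and per-stage wall time.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np

from .config import PipelineConfig
from .io import ImageStack
from .preprocessing import preprocess_slice
from .refinement import refine_slice
from .segmentation import segment_slice

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage and slice where it occurred."""


@dataclass
class RunReport:
    n_slices: int = 0
    directional_convolutions: int = 0
    intersection_ops: int = 0
    membrane_convolutions: int = 0
    stage_seconds: Dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_slices": self.n_slices,
            "directional_convolutions": self.directional_convolutions,
            "intersection_ops": self.intersection_ops,
            "membrane_convolutions": self.membrane_convolutions,
            "stage_seconds": dict(self.stage_seconds),
        }


def run_pipeline(stack: ImageStack,
                 config: PipelineConfig) -> Tuple[List[np.ndarray], RunReport]:
    """Segment Z-disks in every slice of a stack.

    Returns ``(masks, report)`` with one boolean mask per slice, in slice
    order.  Stage errors propagate as :class:`PipelineError` naming the
    stage and slice.
    """
    if stack.n_slices == 0:
        raise ValueError("stack is empty")
    report = RunReport(n_slices=stack.n_slices)
    timers = {"preprocessing": 0.0, "segmentation": 0.0, "refinement": 0.0}
    masks: List[np.ndarray] = []
    for index, raw in enumerate(stack):
        preprocessed = _stage(timers, "preprocessing", index,
                              preprocess_slice, raw, config)
        candidate = _stage(timers, "segmentation", index,
                           segment_slice, preprocessed, config, report)
        refined = _stage(timers, "refinement", index,
                         refine_slice, candidate, preprocessed, raw, config)
        report.membrane_convolutions += 2
        masks.append(refined)
    report.stage_seconds = timers
    logger.info(
        "pipeline: %d slices, %d directional convolutions, %d intersections",
        report.n_slices, report.directional_convolutions, report.intersection_ops)
    return masks, report


def _stage(timers, name, index, fn, *args):
    start = time.perf_counter()
    try:
        return fn(*args)
    except Exception as exc:
        raise PipelineError(f"stage {name!r} failed on slice {index}: {exc}") from exc
    finally:
        timers[name] += time.perf_counter() - start
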