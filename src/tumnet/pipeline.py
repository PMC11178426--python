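"""End-to-end flow: load -> resize -> fuse -> classify -> segment -> report.

With an MRI/CT pair, the two slices are fused pixelwise first and the
classifier and segmenter operate on the fused image; with a single
modality, fusion is skipped. Segmentation runs only when the classifier
calls the slice tumorous (``force_segment`` bypasses the gate for
evaluation runs). Every report embeds the configuration and content
hashes of the inputs, and is deterministic for fixed model, inputs, and
configuration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

from .fusion import MODEL_INPUT_SIDE, fuse, resize_for_model
from .image import GrayImage
from .metrics import MetricsReport, SSIMParams, fusion_report
from .model import ClassificationResult, TumnetModel
from .segmentation import (
    DEFAULT_AREA_FACTOR,
    DEFAULT_MIN_AREA_PX,
    DEFAULT_MIN_SOLIDITY,
    BinaryMask,
    SegmentationResult,
    segment,
)

TUMOR_LABEL = "tumor"


@dataclass
class PipelineConfig:
    """Settings for one pipeline run."""

    fusion_method: str = "average"
    model_path: Optional[str] = None
    threshold_method: str = "otsu"
    threshold: Optional[float] = None
    min_solidity: float = DEFAULT_MIN_SOLIDITY
    min_area_px: int = DEFAULT_MIN_AREA_PX
    area_factor: float = DEFAULT_AREA_FACTOR
    force_segment: bool = False
    normalized_stats: bool = True
    rng_seed: int = 0


@dataclass(frozen=True)
class PipelineReport:
    """Everything one run produced, JSON-serializable."""

    classification: ClassificationResult
    segmentation: Optional[SegmentationResult]
    metrics: MetricsReport
    fused: GrayImage
    provenance: dict

    def to_dict(self) -> dict:
        seg = None
        if self.segmentation is not None:
            seg = {
                "total_tumor_px": self.segmentation.total_tumor_px,
                "tumor_area_mm2": self.segmentation.tumor_area_mm2,
                "threshold": self.segmentation.threshold,
                "components_kept": [asdict(c) for c in self.segmentation.components_kept],
                "components_rejected": [
                    asdict(c) for c in self.segmentation.components_rejected
                ],
            }
        return {
            "classification": {
                "label": self.classification.label,
                "probabilities": self.classification.probabilities,
            },
            "segmentation": seg,
            "metrics": self.metrics.to_dict(),
            "provenance": self.provenance,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)


def _content_hash(img: GrayImage) -> str:
    return hashlib.sha256(img.to_uint8().tobytes()).hexdigest()


def run_pipeline(
    mri: GrayImage,
    ct: Optional[GrayImage] = None,
    model: Optional[TumnetModel] = None,
    cfg: PipelineConfig | None = None,
) -> PipelineReport:
    """Run the full detection flow on one slice (pair).

    ``model`` may be given directly or via ``cfg.model_path``. Returns a
    report whose segmentation block is present iff the slice was called
    tumorous (or segmentation was forced).
    """
    cfg = cfg if cfg is not None else PipelineConfig()
    if model is None:
        if cfg.model_path is None:
            raise ValueError("a trained model (or cfg.model_path) is required")
        model = TumnetModel.load(cfg.model_path)

    provenance: dict = {
        "config": asdict(cfg),
        "inputs": {"mri_sha256": _content_hash(mri)},
    }
    mri_r = resize_for_model(mri)
    if ct is not None:
        mri.require_same_shape(ct)
        provenance["inputs"]["ct_sha256"] = _content_hash(ct)
        ct_r = resize_for_model(ct)
        working = fuse(mri_r, ct_r, cfg.fusion_method).fused
    else:
        ct_r = None
        working = mri_r

    classification = model.classify(working)

    seg: Optional[SegmentationResult] = None
    if classification.label == TUMOR_LABEL or cfg.force_segment:
        seg = segment(
            working,
            method=cfg.threshold_method,
            threshold=cfg.threshold,
            min_solidity=cfg.min_solidity,
            min_area_px=cfg.min_area_px,
            area_factor=cfg.area_factor,
        )

    metrics = fusion_report(
        mri=mri_r if ct is not None else None,
        ct=ct_r,
        fused=working,
        tumor_mask=seg.tumor_mask if seg is not None else None,
        normalized_stats=cfg.normalized_stats,
    )
    return PipelineReport(
        classification=classification,
        segmentation=seg,
        metrics=metrics,
        fused=working,
        provenance=provenance,
    )
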