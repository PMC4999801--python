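"""End-to-end field processing: image in, nucleus table and grading out.

This module wires the stages together once so the CLI, the tests and
the batch runner all execute the identical sequence:

    preprocess -> channel planes -> features -> standardize -> k-means
    -> class identification -> per-class mask cleanup -> chessboard
    watershed -> nucleus table -> field quantification

The nuclear classes are cleaned and split separately, so a DAB nucleus
can never merge with a hematoxylin one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cluster_segment import ClusterModel, segment_features
from .config import PipelineConfig
from .features import assemble_features
from .io_images import CLASS_DAB, CLASS_HEMATOXYLIN, ChannelPlanes, to_channel_planes
from .morphology import LabelledNuclei, clean_mask, split_touching
from .preprocess import PreprocessParams, smooth_enhance
from .quantify import (
    FieldQuantification,
    NucleusRecord,
    build_nucleus_table,
    quantify_field,
    scanline_object_order,
)


@dataclass(frozen=True)
class FieldResult:
    """Everything computed for one field."""

    class_map: np.ndarray                      # (H, W) uint8 of CLASS_*
    labelled: dict[str, LabelledNuclei]        # per nuclear class
    nucleus_labels: np.ndarray                 # combined (H, W) int32, ids unique
    records: list[NucleusRecord]
    quantification: FieldQuantification
    model: ClusterModel
    planes: ChannelPlanes                      # preprocessed planes


def process_field(img: np.ndarray, config: PipelineConfig | None = None) -> FieldResult:
    """Run the full pipeline on one RGB field."""
    config = config or PipelineConfig()
    pp = PreprocessParams(
        window_radius=config.get("preprocess.window_radius"),
        gaussian_sigma=config.get("preprocess.gaussian_sigma"),
    )
    smoothed = smooth_enhance(img, pp)
    planes = to_channel_planes(smoothed)
    fm = assemble_features(planes, excess_kurtosis=config.get("features.excess_kurtosis"))
    class_map, model = segment_features(
        fm,
        seed=config.get("cluster.seed"),
        tol=config.get("cluster.tol"),
        max_iter=config.get("cluster.max_iter"),
        restarts=config.get("cluster.restarts"),
        subsample_n=config.get("cluster.subsample_n"),
    )

    min_area = config.get("morphology.min_area")
    h = config.get("morphology.h_maxima")
    relief = config.get("morphology.relief")
    labelled: dict[str, LabelledNuclei] = {}
    for cls_name, cls_value in (("DAB", CLASS_DAB), ("HEMATOXYLIN", CLASS_HEMATOXYLIN)):
        mask = clean_mask(class_map == cls_value, min_area=min_area)
        labelled[cls_name] = split_touching(mask, h=h, relief=relief)

    # combined label map: same scanline ordering that assigns record ids
    records = build_nucleus_table(labelled, planes.b_plane)
    combined = np.zeros(class_map.shape, dtype=np.int32)
    global_id = {
        key: i + 1 for i, key in enumerate(scanline_object_order(labelled))
    }
    for cls_name, ln in labelled.items():
        if ln.n_objects == 0:
            continue
        lut = np.zeros(ln.n_objects + 1, dtype=np.int32)
        for local in range(1, ln.n_objects + 1):
            lut[local] = global_id.get((cls_name, local), 0)
        combined = np.where(ln.labels > 0, lut[ln.labels], combined)

    quant = quantify_field(records)
    return FieldResult(
        class_map=class_map,
        labelled=labelled,
        nucleus_labels=combined,
        records=records,
        quantification=quant,
        model=model,
        planes=planes,
    )


def field_report(result: FieldResult) -> dict:
    """JSON-ready per-field report."""
    return {
        "field": result.quantification.as_dict(),
        "n_objects": len(result.records),
    }
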