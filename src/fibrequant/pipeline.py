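"""End-to-end analysis of one section: segmentation, morphometrics, quantification.

``analyse_section`` runs the three stages (tissue + artefacts, fibre
segmentation, per-fibre characterisation) and assembles one flat
:class:`FibreRecord` per accepted fibre — the row written to the per-fibre CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .image_io import ChannelStack
from .morphometrics import FibreGeometry, compute_morphometrics
from .myosin import MyosinThreshold, classify_myosin
from .sarcolemmal import FibreStainProfile, PositiveObject, QuantParams, measure_stain_profile
from .segmentation import (FibreLabelMap, FibrePartition, SegmentationParams, TissueMask,
                           detect_tissue, exclude_artefacts, partition_fibres, segment_fibres)
from .summary import SectionSummary, summarise_section


@dataclass
class FibreRecord:
    """One fibre's morphometrics and staining profile (CSV row, field order = column order)."""

    label: int
    centroid_r: float
    centroid_c: float
    fibre_area_um2: float
    sarcoplasm_area_um2: float
    sarcolemma_area_um2: float
    fibre_width_um: float
    sarcoplasm_width_um: float
    mean_ring_thickness_um: float
    max_ring_thickness_um: float
    circumference_um: float
    mask_sarcolemma_mean: float
    mask_sarcoplasm_mean: float
    primary_sarcolemma_mean: float
    primary_sarcoplasm_mean: float
    tertiary_sarcolemma_mean: float
    tertiary_sarcoplasm_mean: float
    primary_threshold: float
    circumference_positivity: float
    coverage_class: str | None
    is_positive: bool | None
    tertiary_mean_in_primary_pos: float
    tertiary_mean_in_primary_neg: float
    myosin_positive: bool | None
    quantifiable: bool


@dataclass
class AnalysisResult:
    records: list[FibreRecord]
    label_map: FibreLabelMap
    partitions: list[FibrePartition]
    tissue: TissueMask
    profiles: list[FibreStainProfile]
    objects: dict[int, list[PositiveObject]]
    rejected: list[tuple[int, str]]
    summary: SectionSummary | None

    @property
    def classes(self) -> dict[int, str]:
        """label -> coverage class for the classification map (quantifiable fibres)."""
        return {r.label: r.coverage_class for r in self.records if r.coverage_class is not None}

    def unrecognised_mask(self) -> np.ndarray:
        """Tissue that ended up in no accepted fibre (connective tissue / misses)."""
        return (self.tissue.tissue | self.tissue.excluded) & (self.label_map.labels == 0)


def _make_record(geom: FibreGeometry, prof: FibreStainProfile,
                 myosin_flag: bool | None) -> FibreRecord:
    return FibreRecord(
        label=geom.label,
        centroid_r=geom.centroid[0],
        centroid_c=geom.centroid[1],
        fibre_area_um2=geom.fibre_area,
        sarcoplasm_area_um2=geom.sarcoplasm_area,
        sarcolemma_area_um2=geom.sarcolemma_area,
        fibre_width_um=geom.fibre_width,
        sarcoplasm_width_um=geom.sarcoplasm_width,
        mean_ring_thickness_um=geom.mean_ring_thickness,
        max_ring_thickness_um=geom.max_ring_thickness,
        circumference_um=geom.circumference,
        mask_sarcolemma_mean=prof.mask_sarcolemma_mean,
        mask_sarcoplasm_mean=prof.mask_sarcoplasm_mean,
        primary_sarcolemma_mean=prof.primary_sarcolemma_mean,
        primary_sarcoplasm_mean=prof.primary_sarcoplasm_mean,
        tertiary_sarcolemma_mean=prof.tertiary_sarcolemma_mean,
        tertiary_sarcoplasm_mean=prof.tertiary_sarcoplasm_mean,
        primary_threshold=prof.positivity_threshold,
        circumference_positivity=prof.circumference_positivity,
        coverage_class=prof.coverage_class,
        is_positive=prof.is_positive,
        tertiary_mean_in_primary_pos=prof.tertiary_mean_in_primary_pos,
        tertiary_mean_in_primary_neg=prof.tertiary_mean_in_primary_neg,
        myosin_positive=myosin_flag,
        quantifiable=prof.quantifiable,
    )


def analyse_section(stack: ChannelStack,
                    seg_params: SegmentationParams | None = None,
                    quant_params: QuantParams | None = None,
                    myosin_threshold: MyosinThreshold | None = None,
                    channel_images: Mapping[str, np.ndarray] | None = None,
                    ) -> AnalysisResult:
    """Run the full pipeline on one loaded section.

    ``myosin_threshold`` enables regeneration calls for sarcoplasmic tertiary
    stains.  ``channel_images`` overrides stain channels for the quantification
    stage only (segmentation always reads the stack's mask channel).
    """
    seg_params = seg_params or SegmentationParams()
    quant_params = quant_params or QuantParams()
    tissue = detect_tissue(stack, seg_params)
    tissue = exclude_artefacts(stack, tissue, seg_params)
    label_map = segment_fibres(stack, tissue, seg_params)
    parts, dropped = partition_fibres(label_map, stack, seg_params)
    records: list[FibreRecord] = []
    profiles: list[FibreStainProfile] = []
    objects: dict[int, list[PositiveObject]] = {}
    for part in parts:
        geom = compute_morphometrics(part, stack.pixel_size)
        prof, objs = measure_stain_profile(part, stack, quant_params, channel_images)
        myosin_flag: bool | None = None
        if stack.tertiary_kind == "sarcoplasmic" and myosin_threshold is not None:
            myosin_flag = classify_myosin(prof, myosin_threshold)
        records.append(_make_record(geom, prof, myosin_flag))
        profiles.append(prof)
        objects[part.label] = objs
    rejected = list(label_map.rejected) + dropped
    summary = None
    if any(r.quantifiable for r in records):
        summary = summarise_section(records, n_rejected=len(rejected),
                                    positivity_cutoff=quant_params.positivity_cutoff)
    return AnalysisResult(
        records=records,
        label_map=label_map,
        partitions=parts,
        tissue=tissue,
        profiles=profiles,
        objects=objects,
        rejected=rejected,
        summary=summary,
    )
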