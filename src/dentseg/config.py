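"""Pipeline configuration: scale presets, clustering parameters, ablations.

Two presets are provided: ``desk`` (tiny networks, small patches - the
scale every test in this repository runs at) and ``paper`` (the full-scale
patch sizes of the original clinical system, retained as named constants;
training at that scale is a GPU-class job and outside the test surface).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


@dataclass
class PipelineConfig:
    scale: str = "desk"
    # preprocessing (raw units; the standard CBCT clip window)
    target_mm: float = 0.4
    clip_lo: float = 0.0
    clip_hi: float = 2500.0
    # dense-network inference tiling; the desk networks are fully
    # convolutional, so whole desk-scale volumes go through in one window
    # (window borders predict worse than interiors, so fewer seams is better)
    net_patch: tuple[int, int, int] = (48, 48, 48)
    overlap_fraction: float = 0.25
    # ROI stage
    roi_threshold: float = 0.5
    roi_min_component: int = 20
    roi_margin: int = 4
    # density-peaks clustering (voxel units at 0.4 mm)
    cluster_dc: float = 2.0
    cluster_min_density: int = 20
    cluster_min_sep: float = 5.0
    cluster_min_votes: int = 100  # reject stray clusters far below tooth-sized support
    # single-tooth stage
    tooth_patch: tuple[int, int, int] = (24, 24, 24)
    sigma_centroid: float = 2.0
    mask_threshold: float = 0.5
    # FDI source: arch-geometry heuristic or the classifier head
    fdi_source: str = "heuristic"
    # ablation switches
    no_skeleton: bool = False
    no_multitask: bool = False
    no_haar: bool = False
    # model checkpoint paths (ignored in oracle mode)
    model_paths: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.scale not in ("desk", "paper"):
            raise ValueError(f"scale must be 'desk' or 'paper', got {self.scale!r}")
        if self.fdi_source not in ("heuristic", "classifier"):
            raise ValueError(f"unknown fdi_source {self.fdi_source!r}")
        if self.clip_hi <= self.clip_lo:
            raise ValueError("clip_hi must exceed clip_lo")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["net_patch"] = list(self.net_patch)
        d["tooth_patch"] = list(self.tooth_patch)
        return d


def desk_config(**overrides) -> PipelineConfig:
    return PipelineConfig(**overrides)


def paper_config(**overrides) -> PipelineConfig:
    """Full-scale preset: 256^3 dense patches, 96^3 single-tooth crops."""
    defaults = dict(
        scale="paper",
        net_patch=(256, 256, 256),
        tooth_patch=(96, 96, 96),
    )
    defaults.update(overrides)
    return PipelineConfig(**defaults)
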