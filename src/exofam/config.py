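"""Thresholds, scoring weights and YAML configuration handling.

Precedence when resolving a run configuration: CLI flag > YAML file >
built-in default. The resolved configuration is echoed into the run log
so every reported number can be traced to the settings that produced it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Any, Mapping, Optional

import yaml

from .model import InheritanceModel, ValidationError


@dataclass(frozen=True)
class Thresholds:
    """Numeric cutoffs used across the cascade and scoring.

    maf_exclusion
        Variants with any present database MAF >= this are excluded
        (inclusive boundary).
    rare_maf
        Strict upper bound for the "rare" frequency class (< 1/1000).
    dann_damaging
        DANN counts as a damaging call at or above this score.
    min_damaging_tools
        Minimum damaging-tool count for the multi-tool pathogenicity
        bit ("more than two" => 3).
    unaffected_se_max_abs
        Both-eye |SE| bound (diopters) below which a member is
        phenotypically unaffected.
    hm_se_max
        Worst-eye spherical equivalent at or below which a member is
        high-myopic (diopters; more negative is worse).
    hm_al_min
        Longest axial length strictly above which a member is
        high-myopic (mm).
    """

    maf_exclusion: float = 0.01
    rare_maf: float = 0.001
    dann_damaging: float = 0.90
    min_damaging_tools: int = 3
    unaffected_se_max_abs: float = 2.00
    hm_se_max: float = -6.00
    hm_al_min: float = 26.00

    def __post_init__(self) -> None:
        if not (0.0 < self.rare_maf < self.maf_exclusion <= 1.0):
            raise ValidationError(
                "thresholds must satisfy 0 < rare_maf < maf_exclusion <= 1; got "
                f"rare_maf={self.rare_maf}, maf_exclusion={self.maf_exclusion}"
            )
        if self.min_damaging_tools < 1:
            raise ValidationError("min_damaging_tools must be >= 1")
        if not (0.0 <= self.dann_damaging <= 1.0):
            raise ValidationError("dann_damaging must be in [0, 1]")


#: Evidence-matrix category names in fixed report order.
CATEGORY_ORDER = (
    "known_hm_gene",
    "hm_related_gene",
    "ocular_disease_gene",
    "at_myp_locus",
    "multi_tool_damaging",
    "exonic_protein_altering",
    "non_protein_altering",
    "expressed_adult_ocular",
    "expressed_embryonic_ocular",
    "freq_novel",
    "freq_rare",
)

#: Default category weights. Every informative bit counts 1.0;
#: non_protein_altering is the complement of the exonic bit and carries
#: no weight; a rare (but reported) frequency counts half a novel one.
DEFAULT_WEIGHTS: dict[str, float] = {
    "known_hm_gene": 1.0,
    "hm_related_gene": 1.0,
    "ocular_disease_gene": 1.0,
    "at_myp_locus": 1.0,
    "multi_tool_damaging": 1.0,
    "exonic_protein_altering": 1.0,
    "non_protein_altering": 0.0,
    "expressed_adult_ocular": 1.0,
    "expressed_embryonic_ocular": 1.0,
    "freq_novel": 1.0,
    "freq_rare": 0.5,
}

#: Mapping from a sorted tuple of ACMG tags to a classification. With
#: only PM2/PP1/PP3 available (one moderate + two supporting), the
#: published combining rules cannot reach likely_pathogenic; any
#: non-empty tag set is therefore uncertain_significance.
DEFAULT_ACMG_TABLE: dict[frozenset[str], str] = {frozenset(): "likely_benign"}
DEFAULT_ACMG_FALLBACK = "uncertain_significance"


@dataclass
class RunConfig:
    thresholds: Thresholds = field(default_factory=Thresholds)
    weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    collapse_polyphen: bool = True
    top_k: int = 20
    inheritance_overrides: dict[str, InheritanceModel] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.weights) - set(CATEGORY_ORDER)
        if unknown:
            raise ValidationError(f"unknown weight categories: {sorted(unknown)}")
        missing = set(CATEGORY_ORDER) - set(self.weights)
        if missing:
            raise ValidationError(f"missing weight categories: {sorted(missing)}")
        if any(w < 0 for w in self.weights.values()):
            raise ValidationError("category weights must be non-negative")

    def describe(self) -> dict[str, Any]:
        d = asdict(self)
        d["inheritance_overrides"] = {
            k: v.value for k, v in self.inheritance_overrides.items()
        }
        return d


def load_config(path: Optional[str] = None, **overrides: Any) -> RunConfig:
    """Build a :class:`RunConfig` from an optional YAML file plus overrides.

    The YAML file may contain ``thresholds:``, ``weights:``,
    ``collapse_polyphen:``, ``top_k:`` and ``inheritance_overrides:``
    sections; keyword overrides win over file values.
    """
    data: Mapping[str, Any] = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, Mapping):
            raise ValidationError(f"config file {path} must contain a mapping")

    thr_kwargs = dict(data.get("thresholds", {}))
    thr_kwargs.update(overrides.pop("thresholds", {}))
    thresholds = Thresholds(**thr_kwargs)

    weights = dict(DEFAULT_WEIGHTS)
    weights.update(data.get("weights", {}))
    weights.update(overrides.pop("weights", {}))

    inh = {
        str(fam): InheritanceModel(model)
        for fam, model in dict(data.get("inheritance_overrides", {})).items()
    }
    inh.update(overrides.pop("inheritance_overrides", {}))

    cfg = RunConfig(
        thresholds=thresholds,
        weights=weights,
        collapse_polyphen=bool(data.get("collapse_polyphen", True)),
        top_k=int(data.get("top_k", 20)),
        inheritance_overrides=inh,
    )
    for key, value in overrides.items():
        if not hasattr(cfg, key):
            raise ValidationError(f"unknown config override {key!r}")
        setattr(cfg, key, value)
    return cfg


def with_thresholds(cfg: RunConfig, **kwargs: Any) -> RunConfig:
    """Return a copy of ``cfg`` with some threshold fields replaced."""
    new = RunConfig(
        thresholds=replace(cfg.thresholds, **kwargs),
        weights=dict(cfg.weights),
        collapse_polyphen=cfg.collapse_polyphen,
        top_k=cfg.top_k,
        inheritance_overrides=dict(cfg.inheritance_overrides),
    )
    return new
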