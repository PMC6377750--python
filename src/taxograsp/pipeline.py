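"""End-to-end taxonomy construction and comparison.

The pipeline realizes the three-level merge hierarchy:

1. per subject, modality and feature family: windowed features ->
   MANOVA-pooled Mahalanobis distances between grasps -> agglomerative
   dendrogram -> rooted unweighted tree;
2. per modality and family: the subject trees are merged into a
   *feature supertree* by SPR-distance minimization;
3. per modality: the five feature supertrees merge into the modality
   taxonomy (muscular for EMG, kinematic for the glove), and the two
   modality taxonomies merge into the general taxonomy.

``compare_taxonomies`` then summarizes the bundle with tree edit
distances: between the two modality taxonomies, between each modality
taxonomy and its feature supertrees, between the general taxonomy and the
modality taxonomies, plus inter-subject (per modality x family) and
intra-subject (across families) pair statistics.  For audit of
best-effort reproduction runs on the real 40-subject Ninapro DB2 corpus,
the report can attach the reference edit distances reported for that
full-scale analysis next to the computed values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .cluster import LINKAGES, agglomerate, to_phylo
from .distance import grasp_distances
from .features import FAMILIES, FeatureSpec, build_feature_table
from .io_formats import GraspSet, SignalRecording, default_grasp_set
from .metrics import pairwise_stats, robinson_foulds, tree_edit_distance
from .phylo import PhyloTree
from .preprocessing import hampel_powerline_filter, segment_windows, synchronize
from .supertree import build_supertree

__all__ = ["RunConfig", "TaxonomyBundle", "run_taxonomy", "compare_taxonomies",
           "planted_tree_recovery", "REFERENCE_FULL_SCALE"]

log = logging.getLogger(__name__)

MODALITIES = ("emg", "glove")

# Reference edit distances for the full-scale analysis of the 40-subject
# Ninapro DB2 corpus (20 grasps), used to print an audit column next to
# the values a best-effort reproduction run computes.
REFERENCE_FULL_SCALE = {
    ("modality_vs_modality", "emg", "glove"): 33,
    ("taxonomy_vs_feature", "emg", "IAV"): 22,
    ("taxonomy_vs_feature", "emg", "MAV"): 22,
    ("taxonomy_vs_feature", "emg", "RMS"): 34,
    ("taxonomy_vs_feature", "emg", "TD"): 24,
    ("taxonomy_vs_feature", "emg", "WL"): 39,
    ("taxonomy_vs_feature", "glove", "IAV"): 19,
    ("taxonomy_vs_feature", "glove", "MAV"): 31,
    ("taxonomy_vs_feature", "glove", "RMS"): 0,
    ("taxonomy_vs_feature", "glove", "TD"): 34,
    ("taxonomy_vs_feature", "glove", "WL"): 26,
    ("general_vs_modality", "emg", ""): 29,
    ("general_vs_modality", "glove", ""): 42,
}


@dataclass
class RunConfig:
    """All knobs of one taxonomy run; serialized alongside outputs."""

    grasp_set: GraspSet = None
    families: tuple = FAMILIES
    modalities: tuple = MODALITIES
    window_ms: float = 200.0
    overlap_ms: float = 100.0
    zc_threshold: float = 0.0
    ssc_threshold: float = 0.0
    linkage: str = "average"
    ridge: float = 1e-6
    k_max: int = 12
    max_iter: int = 100
    target_fs: float = 2000.0
    apply_hampel: bool = True
    powerline_hz: float = 50.0
    field_map: dict = None
    seed: int = 0

    def __post_init__(self):
        if self.grasp_set is None:
            self.grasp_set = default_grasp_set(20)
        self.families = tuple(self.families)
        self.modalities = tuple(self.modalities)
        unknown = set(self.families) - set(FAMILIES)
        if unknown:
            raise ValueError(f"unknown feature families {sorted(unknown)}")
        unknown = set(self.modalities) - set(MODALITIES)
        if unknown:
            raise ValueError(f"unknown modalities {sorted(unknown)}")
        if self.linkage not in LINKAGES:
            raise ValueError(f"linkage must be one of {LINKAGES}")
        if self.window_ms <= self.overlap_ms:
            raise ValueError("window_ms must exceed overlap_ms")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grasp_set"] = {"grasp_ids": list(self.grasp_set.grasp_ids),
                          "grasp_names": list(self.grasp_set.grasp_names)}
        return d


@dataclass
class TaxonomyBundle:
    """All trees and matrices produced by one run of the pipeline."""

    subject_trees: dict = field(default_factory=dict)      # (subject, modality, family) -> PhyloTree
    feature_supertrees: dict = field(default_factory=dict)  # (modality, family) -> PhyloTree
    modality_taxonomies: dict = field(default_factory=dict)  # modality -> PhyloTree
    general_taxonomy: PhyloTree = None
    distance_matrices: dict = field(default_factory=dict)  # (subject, modality, family) -> GraspDistanceMatrix
    edit_distance_report: pd.DataFrame = None
    config: RunConfig = None

    @property
    def subjects(self) -> list:
        return sorted({s for s, _, _ in self.subject_trees})

    def all_trees(self):
        yield from self.subject_trees.values()
        yield from self.feature_supertrees.values()
        yield from self.modality_taxonomies.values()
        if self.general_taxonomy is not None:
            yield self.general_taxonomy


def subject_tree(recording: SignalRecording, config: RunConfig) -> dict:
    """Per-subject stage: one tree and one distance matrix per modality x family.

    Returns ``{"trees": {(modality, family): PhyloTree},
    "distances": {(modality, family): GraspDistanceMatrix}}``.
    """
    cfg = config
    rec = recording
    if cfg.apply_hampel:
        rec = SignalRecording(
            subject_id=rec.subject_id,
            emg=hampel_powerline_filter(rec.emg, rec.fs_emg, cfg.powerline_hz),
            glove=rec.glove,
            stimulus=rec.stimulus,
            repetition=rec.repetition,
            timestamps_emg=rec.timestamps_emg,
            timestamps_glove=rec.timestamps_glove,
            fs_emg=rec.fs_emg,
            fs_glove=rec.fs_glove,
        )
    rec = synchronize(rec, target_fs=cfg.target_fs)
    windows = segment_windows(rec, cfg.window_ms, cfg.overlap_ms, cfg.grasp_set,
                              modalities=cfg.modalities)
    by_mod = {m: [w for w in windows if w.modality == m] for m in cfg.modalities}

    trees = {}
    distances = {}
    for modality in cfg.modalities:
        for family in cfg.families:
            spec = FeatureSpec(family=family, zc_threshold=cfg.zc_threshold,
                               ssc_threshold=cfg.ssc_threshold)
            table = build_feature_table(by_mod[modality], spec)
            dmat = grasp_distances(table, cfg.grasp_set, ridge=cfg.ridge)
            if dmat.regularized:
                log.info("ridge regularization fired: subject=%s modality=%s "
                         "family=%s", rec.subject_id, modality, family)
            trees[(modality, family)] = to_phylo(agglomerate(dmat, cfg.linkage))
            distances[(modality, family)] = dmat
    return {"trees": trees, "distances": distances, "subject": rec.subject_id}


def run_taxonomy(recordings, config: RunConfig = None) -> TaxonomyBundle:
    """Run the full three-level merge over an iterable of recordings.

    ``recordings`` may be :class:`SignalRecording` objects or paths readable
    by :func:`taxograsp.io_formats.read_recording`.  Deterministic given the
    configuration.
    """
    from .io_formats import read_recording

    cfg = config or RunConfig()
    bundle = TaxonomyBundle(config=cfg)

    n_subjects = 0
    for rec in recordings:
        if not isinstance(rec, SignalRecording):
            rec = read_recording(rec, field_map=cfg.field_map)
        n_subjects += 1
        try:
            result = subject_tree(rec, cfg)
        except Exception as exc:
            raise RuntimeError(
                f"subject {rec.subject_id}: {exc}"
            ) from exc
        for key, tree in result["trees"].items():
            bundle.subject_trees[(result["subject"],) + key] = tree
        for key, dmat in result["distances"].items():
            bundle.distance_matrices[(result["subject"],) + key] = dmat
    if n_subjects < 2:
        raise ValueError("need at least two subjects")
    if len(cfg.grasp_set) < 3:
        raise ValueError("need at least three grasps")

    subjects = bundle.subjects
    for modality in cfg.modalities:
        for family in cfg.families:
            inputs = [bundle.subject_trees[(s, modality, family)] for s in subjects]
            try:
                res = build_supertree(inputs, k_max=cfg.k_max, max_iter=cfg.max_iter)
            except Exception as exc:
                raise RuntimeError(f"feature supertree {modality}/{family}: {exc}") from exc
            bundle.feature_supertrees[(modality, family)] = res.tree
        mod_inputs = [bundle.feature_supertrees[(modality, f)] for f in cfg.families]
        res = build_supertree(mod_inputs, k_max=cfg.k_max, max_iter=cfg.max_iter)
        bundle.modality_taxonomies[modality] = res.tree

    general_inputs = [bundle.modality_taxonomies[m] for m in cfg.modalities]
    res = build_supertree(general_inputs, k_max=cfg.k_max, max_iter=cfg.max_iter)
    bundle.general_taxonomy = res.tree

    # mean Mahalanobis matrix across subjects and families, per modality
    # (reporting only; trees are always built per feature)
    for modality in cfg.modalities:
        mats = [bundle.distance_matrices[(s, modality, f)]
                for s in subjects for f in cfg.families]
        mean_d = np.mean([m.d for m in mats], axis=0)
        from .distance import GraspDistanceMatrix
        bundle.distance_matrices[f"mean_{modality}"] = GraspDistanceMatrix(
            labels=mats[0].labels, d=mean_d,
            n_per_group=mats[0].n_per_group,
            metadata={"modality": modality, "aggregate": "mean"},
        )

    bundle.edit_distance_report = compare_taxonomies(bundle)
    return bundle


def compare_taxonomies(bundle: TaxonomyBundle, include_reference: bool = True
                       ) -> pd.DataFrame:
    """Edit-distance summary of a bundle.

    Sections of the returned frame:

    * ``modality_vs_modality`` — TED between the two modality taxonomies;
    * ``taxonomy_vs_feature`` — TED between each modality taxonomy and each
      of its feature supertrees;
    * ``general_vs_modality`` — TED between the general taxonomy and each
      modality taxonomy;
    * ``inter_subject`` — mean +/- SD of pairwise TED over subjects'
      trees, per modality x family;
    * ``intra_subject`` — mean +/- SD of pairwise TED across the family
      trees of each subject, per modality.

    When ``include_reference`` is set, rows for which full-scale reference
    values exist carry them in a ``reference`` column.
    """
    cfg = bundle.config
    rows = []

    def add(section, modality, family, subject, value, sd=np.nan):
        ref = REFERENCE_FULL_SCALE.get((section, modality, family), np.nan) \
            if include_reference else np.nan
        rows.append({"section": section, "modality": modality, "family": family,
                     "subject": subject, "value": value, "sd": sd,
                     "reference": ref})

    mods = list(bundle.modality_taxonomies)
    if len(mods) == 2:
        add("modality_vs_modality", mods[0], mods[1], "",
            tree_edit_distance(bundle.modality_taxonomies[mods[0]],
                               bundle.modality_taxonomies[mods[1]]))
    for modality in mods:
        for family in cfg.families:
            add("taxonomy_vs_feature", modality, family, "",
                tree_edit_distance(bundle.modality_taxonomies[modality],
                                   bundle.feature_supertrees[(modality, family)]))
    for modality in mods:
        add("general_vs_modality", modality, "", "",
            tree_edit_distance(bundle.general_taxonomy,
                               bundle.modality_taxonomies[modality]))
    subjects = bundle.subjects
    for modality in mods:
        for family in cfg.families:
            trees = [bundle.subject_trees[(s, modality, family)] for s in subjects]
            if len(trees) >= 2:
                mean, sd = pairwise_stats(trees)
                add("inter_subject", modality, family, "", mean, sd)
        for subject in subjects:
            trees = [bundle.subject_trees[(subject, modality, f)]
                     for f in cfg.families]
            if len(trees) >= 2:
                mean, sd = pairwise_stats(trees)
                add("intra_subject", modality, "", subject, mean, sd)
    return pd.DataFrame(rows)


def planted_tree_recovery(bundle: TaxonomyBundle, planted: PhyloTree) -> dict:
    """Robinson–Foulds distance of every bundle tree to the planted tree."""
    out = {}
    for key, tree in bundle.subject_trees.items():
        out[("subject",) + key] = robinson_foulds(tree, planted)
    for key, tree in bundle.feature_supertrees.items():
        out[("feature",) + key] = robinson_foulds(tree, planted)
    for mod, tree in bundle.modality_taxonomies.items():
        out[("modality", mod)] = robinson_foulds(tree, planted)
    out[("general",)] = robinson_foulds(bundle.general_taxonomy, planted)
    return out
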