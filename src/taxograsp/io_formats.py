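"""Reading Ninapro-style recordings and reading/writing trees and reports.

A recording is a MAT-style matrix container holding, per subject, a surface
EMG matrix (samples x channels at ~2 kHz), a data-glove matrix (samples x
sensors, values proportional to joint angles, ~25 Hz in the raw device
stream), a per-sample movement label (``stimulus``, 0 = rest) and a
per-sample repetition index.  Field names inside the container are
configurable through a ``field_map``; the defaults follow the Ninapro DB2
conventions with the re-labelled movement boundaries (``restimulus`` /
``rerepetition``).

Trees are serialised as Newick with branch lengths omitted (the pipeline's
trees have unweighted edges).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import scipy.io

from .phylo import PhyloTree

__all__ = [
    "SignalRecording",
    "GraspSet",
    "FormatError",
    "RecordingValidationError",
    "DEFAULT_FIELD_MAP",
    "NINAPRO_DB2_GRASPS",
    "default_grasp_set",
    "read_recording",
    "write_recording",
    "read_newick",
    "write_newick",
    "parse_newick",
    "write_report",
]


class FormatError(ValueError):
    """A mandatory array is missing from a recording container."""


class RecordingValidationError(ValueError):
    """Arrays are present but mutually inconsistent (e.g. length mismatch)."""


DEFAULT_FIELD_MAP = {
    "emg": "emg",
    "glove": "glove",
    "stimulus": "restimulus",
    "repetition": "rerepetition",
    "timestamps_emg": "timestamps_emg",
    "timestamps_glove": "timestamps_glove",
}

# The 20 grasps analysed by the taxonomy, by their common names in the
# grasping literature.  The mapping from container stimulus integers to
# names is configuration: the default assigns ids 1..20 in this order and
# should be overridden to match the label coding of a concrete dataset.
NINAPRO_DB2_GRASPS = (
    "large diameter",
    "small diameter",
    "medium wrap",
    "fixed hook",
    "stick",
    "lateral",
    "extension type",
    "power disk",
    "power sphere",
    "three finger sphere",
    "precision sphere",
    "tripod",
    "prismatic four fingers",
    "writing tripod",
    "parallel extension",
    "prismatic pinch",
    "tip pinch",
    "quadpod",
    "ring",
    "index finger extension",
)


@dataclass(frozen=True)
class GraspSet:
    """Ordered set of movement labels under analysis.

    ``grasp_ids`` are the integer stimulus codes in the recording;
    ``grasp_names`` are the display names used as tree leaf labels.
    """

    grasp_ids: tuple
    grasp_names: tuple

    def __post_init__(self):
        ids = tuple(int(i) for i in self.grasp_ids)
        names = tuple(str(n) for n in self.grasp_names)
        object.__setattr__(self, "grasp_ids", ids)
        object.__setattr__(self, "grasp_names", names)
        if len(set(ids)) != len(ids):
            raise ValueError("grasp ids must be unique")
        if len(set(names)) != len(names):
            raise ValueError("grasp names must be unique")
        if len(ids) != len(names):
            raise ValueError("grasp_ids and grasp_names must have equal length")
        if any(i == 0 for i in ids):
            raise ValueError("stimulus id 0 is reserved for rest")

    def __len__(self) -> int:
        return len(self.grasp_ids)

    def name_of(self, grasp_id: int) -> str:
        return self.grasp_names[self.grasp_ids.index(int(grasp_id))]

    def subset(self, n: int) -> "GraspSet":
        return GraspSet(self.grasp_ids[:n], self.grasp_names[:n])


def default_grasp_set(n: int = 20) -> GraspSet:
    """GraspSet with ids 1..n over the 20 canonical grasp names."""
    if not 1 <= n <= len(NINAPRO_DB2_GRASPS):
        raise ValueError(f"n must be in 1..{len(NINAPRO_DB2_GRASPS)}")
    return GraspSet(tuple(range(1, n + 1)), NINAPRO_DB2_GRASPS[:n])


@dataclass
class SignalRecording:
    """One subject's multi-modal recording with labels and timestamps.

    ``stimulus`` and ``repetition`` are aligned to the EMG samples.  After
    :func:`taxograsp.preprocessing.synchronize` both modalities live on one
    common time grid and the glove arrays match the EMG arrays in length.
    """

    subject_id: str
    emg: np.ndarray
    glove: np.ndarray
    stimulus: np.ndarray
    repetition: np.ndarray
    timestamps_emg: np.ndarray = None
    timestamps_glove: np.ndarray = None
    fs_emg: float = 2000.0
    fs_glove: float = 25.0

    def __post_init__(self):
        self.emg = np.atleast_2d(np.asarray(self.emg, dtype=float))
        self.glove = np.atleast_2d(np.asarray(self.glove, dtype=float))
        self.stimulus = np.asarray(self.stimulus).ravel().astype(int)
        self.repetition = np.asarray(self.repetition).ravel().astype(int)
        if self.timestamps_emg is None:
            self.timestamps_emg = np.arange(self.emg.shape[0]) / self.fs_emg
        if self.timestamps_glove is None:
            self.timestamps_glove = np.arange(self.glove.shape[0]) / self.fs_glove
        self.timestamps_emg = np.asarray(self.timestamps_emg, dtype=float).ravel()
        self.timestamps_glove = np.asarray(self.timestamps_glove, dtype=float).ravel()
        self.validate()

    def validate(self) -> None:
        if self.emg.shape[0] != self.timestamps_emg.shape[0]:
            raise RecordingValidationError(
                f"emg has {self.emg.shape[0]} samples but timestamps_emg has "
                f"{self.timestamps_emg.shape[0]}"
            )
        if self.glove.shape[0] != self.timestamps_glove.shape[0]:
            raise RecordingValidationError(
                f"glove has {self.glove.shape[0]} samples but timestamps_glove "
                f"has {self.timestamps_glove.shape[0]}"
            )
        if self.stimulus.shape[0] != self.emg.shape[0]:
            raise RecordingValidationError(
                f"stimulus length {self.stimulus.shape[0]} != emg sample count "
                f"{self.emg.shape[0]}"
            )
        if self.repetition.shape[0] != self.stimulus.shape[0]:
            raise RecordingValidationError(
                "repetition length differs from stimulus length"
            )
        for name, ts in (("timestamps_emg", self.timestamps_emg),
                         ("timestamps_glove", self.timestamps_glove)):
            if ts.size > 1 and not np.all(np.diff(ts) > 0):
                raise RecordingValidationError(f"{name} not strictly increasing")

    @property
    def n_emg_channels(self) -> int:
        return self.emg.shape[1]

    @property
    def n_glove_sensors(self) -> int:
        return self.glove.shape[1]


def read_recording(path, field_map: dict | None = None, *, subject_id: str | None = None,
                   fs_emg: float = 2000.0, fs_glove: float = 25.0) -> SignalRecording:
    """Read one subject's recording from a MAT-style container.

    Missing timestamp arrays are synthesized from the stated sampling
    rates.  A glove matrix with the same sample count as the EMG matrix is
    taken to be already on the EMG time grid (the Ninapro DB2 distribution
    ships glove data upsampled to 2 kHz).
    """
    fmap = dict(DEFAULT_FIELD_MAP)
    if field_map:
        fmap.update(field_map)
    mat = scipy.io.loadmat(os.fspath(path), squeeze_me=False)

    def fetch(key, required=True):
        name = fmap[key]
        if name not in mat:
            if required:
                raise FormatError(f"container {path} is missing field {name!r} ({key})")
            return None
        return np.asarray(mat[name])

    emg = fetch("emg")
    glove = fetch("glove")
    stimulus = fetch("stimulus")
    repetition = fetch("repetition")
    ts_emg = fetch("timestamps_emg", required=False)
    ts_glove = fetch("timestamps_glove", required=False)

    if ts_glove is None and glove.shape[0] == emg.shape[0]:
        # glove already on the EMG grid
        fs_glove = fs_emg
    if subject_id is None:
        if "subject" in mat:
            raw = np.asarray(mat["subject"]).ravel()
            subject_id = str(raw[0]) if raw.size else ""
        else:
            subject_id = os.path.splitext(os.path.basename(path))[0]
    return SignalRecording(
        subject_id=subject_id,
        emg=emg,
        glove=glove,
        stimulus=stimulus,
        repetition=repetition,
        timestamps_emg=None if ts_emg is None else ts_emg,
        timestamps_glove=None if ts_glove is None else ts_glove,
        fs_emg=fs_emg,
        fs_glove=fs_glove,
    )


def write_recording(rec: SignalRecording, path, field_map: dict | None = None) -> None:
    """Write a recording to a MAT container (inverse of :func:`read_recording`)."""
    fmap = dict(DEFAULT_FIELD_MAP)
    if field_map:
        fmap.update(field_map)
    scipy.io.savemat(
        os.fspath(path),
        {
            fmap["emg"]: rec.emg,
            fmap["glove"]: rec.glove,
            fmap["stimulus"]: rec.stimulus.reshape(-1, 1),
            fmap["repetition"]: rec.repetition.reshape(-1, 1),
            fmap["timestamps_emg"]: rec.timestamps_emg.reshape(-1, 1),
            fmap["timestamps_glove"]: rec.timestamps_glove.reshape(-1, 1),
            "subject": rec.subject_id,
        },
    )


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

_NEEDS_QUOTE = set("(),:;'[] \t\n")


def _quote(label: str) -> str:
    if any(ch in _NEEDS_QUOTE for ch in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _node_newick(node) -> str:
    if isinstance(node, str):
        return _quote(node)
    return "(" + ",".join(_node_newick(c) for c in node) + ")"


def tree_to_newick(tree: PhyloTree) -> str:
    """Canonical Newick string with labels quoted where required."""
    return _node_newick(tree.root) + ";"


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string into a :class:`PhyloTree`.

    Branch lengths and internal-node labels are discarded (edges are
    unweighted, internal nodes anonymous).  Malformed input raises a parse
    error carrying the offending position, courtesy of dendropy.
    """
    import dendropy

    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises schema-specific errors
        raise ValueError(f"malformed Newick: {exc}") from exc

    def convert(dnode):
        children = dnode.child_nodes()
        if not children:
            if dnode.taxon is None or not dnode.taxon.label:
                raise ValueError("malformed Newick: unlabeled leaf")
            return dnode.taxon.label
        if len(children) == 1:
            return convert(children[0])
        return tuple(convert(c) for c in children)

    return PhyloTree(convert(dtree.seed_node))


def read_newick(path) -> PhyloTree:
    with open(path) as fh:
        return parse_newick(fh.read())


def write_newick(tree: PhyloTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree_to_newick(tree) + "\n")


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------

def write_report(bundle, out_dir) -> None:
    """Write a taxonomy bundle as Newick files and TSV tables.

    Layout::

        out_dir/
          taxonomy_general.nwk
          taxonomy_<modality>.nwk
          supertree_<modality>_<family>.nwk
          subject_trees/<subject>_<modality>_<family>.nwk
          distance_matrices/<subject>_<modality>_<family>.tsv
          distance_matrices/mean_<modality>.tsv
          edit_distances.tsv

    ``bundle`` is a :class:`taxograsp.pipeline.TaxonomyBundle`.
    """
    if not getattr(bundle, "subject_trees", None):
        raise ValueError("cannot write a report for an empty bundle")
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    sub_dir = os.path.join(out_dir, "subject_trees")
    mat_dir = os.path.join(out_dir, "distance_matrices")
    os.makedirs(sub_dir, exist_ok=True)
    os.makedirs(mat_dir, exist_ok=True)

    def slug(s):
        return str(s).replace(" ", "_")

    write_newick(bundle.general_taxonomy, os.path.join(out_dir, "taxonomy_general.nwk"))
    for modality, tree in bundle.modality_taxonomies.items():
        write_newick(tree, os.path.join(out_dir, f"taxonomy_{slug(modality)}.nwk"))
    for (modality, fam), tree in bundle.feature_supertrees.items():
        write_newick(tree, os.path.join(out_dir, f"supertree_{slug(modality)}_{fam}.nwk"))
    for (subject, modality, fam), tree in bundle.subject_trees.items():
        name = f"{slug(subject)}_{slug(modality)}_{fam}.nwk"
        write_newick(tree, os.path.join(sub_dir, name))
    for key, dm in bundle.distance_matrices.items():
        if isinstance(key, tuple):
            name = "_".join(slug(k) for k in key) + ".tsv"
        else:
            name = slug(key) + ".tsv"
        dm.to_frame().to_csv(os.path.join(mat_dir, name), sep="\t")
    if bundle.edit_distance_report is not None:
        bundle.edit_distance_report.to_csv(
            os.path.join(out_dir, "edit_distances.tsv"), sep="\t", index=False
        )
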