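"""Orchestration of the two proposal paths and model/file I/O.

The dictionary path handles arbitrary images: oversegment, describe and
classify superpixels, fuse LV-labeled regions into candidates, and emit 9
scale-adaptive anchors per candidate (scale factors 0.8/0.9).  The tracker
path handles a slice sequence of one individual: seed a correlation-filter
tracker with a detection box on the first slice and emit 9 anchors per
subsequent frame from the tracked box (scale factors 1.1/1.2), with no
dictionary work after the seed frame.  Anchors go out as CSV for any
downstream region-proposal consumer.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import anchors as anchor_mod
from .anchors import Anchor, AnchorConfig, saliency_anchor, scale_adaptive_anchors
from .dictionary import DictionaryClassifier, DiscriminativeDictionary
from .evaluation import DetectionBox
from .fusion import CandidateRegion, fuse
from .superpixels import (
    RegionFeaturizer,
    build_training_classes,
    extract_features,
    oversegment,
)
from .tracker import BlockTracker, TrackerConfig, TrackingError

logger = logging.getLogger("lvprop")

__all__ = [
    "RunConfig",
    "DictionaryProposalModel",
    "run_propose_dict",
    "run_propose_track",
    "anchors_to_dataframe",
    "save_model",
    "load_model",
    "load_image",
    "load_frames",
]

ANCHOR_COLUMNS = [
    "frame", "candidate", "x1", "y1", "x2", "y2", "tag",
    "n_star", "p1_y", "p1_x", "pt_y", "pt_x",
]


@dataclass
class RunConfig:
    """Every tunable default of the pipeline, overridable from YAML."""

    n_superpixels: int = 400  # M
    compactness: float = 0.1
    pca_dims: int = 64
    n_classes: int = 7
    overlap_threshold: float = 0.5
    n_atoms: int = 32
    eps1: float = 0.1
    eps2: float = 0.001
    eta1: float = 0.1
    eta2: float = 0.005
    dict_max_iter: int = 20
    dict_tol: float = 1e-4
    min_candidate_area: int = 20
    dict_scales: tuple[float, float] = (0.8, 0.9)
    track_scales: tuple[float, float] = (1.1, 1.2)
    n_perturb: int = 0
    lam: float = 0.01
    theta: float = 0.025
    scale_step: float = 1.02
    n_scales: int = 33
    w1: float = 0.2
    w2: float = 0.8
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("dict_scales", "track_scales"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def tracker_config(self) -> TrackerConfig:
        return TrackerConfig(
            lam=self.lam, theta=self.theta, scale_step=self.scale_step,
            n_scales=self.n_scales, w1=self.w1, w2=self.w2,
        )

    def log_defaults(self) -> None:
        logger.info("run configuration: %s", asdict(self))


class DictionaryProposalModel:
    """Trained dictionary-path proposer: featurizer + classifier + config."""

    def __init__(self, config: RunConfig | None = None):
        self.config = config or RunConfig()
        self.featurizer: RegionFeaturizer | None = None
        self.classifier: DictionaryClassifier | None = None

    def fit(
        self, images: list[np.ndarray], masks: list[np.ndarray]
    ) -> "DictionaryProposalModel":
        cfg = self.config
        cfg.log_defaults()
        partitions = [
            oversegment(im, cfg.n_superpixels, cfg.compactness) for im in images
        ]
        raw = np.vstack(
            [extract_features(im, p) for im, p in zip(images, partitions)]
        )
        self.featurizer = RegionFeaturizer(n_components=cfg.pca_dims).fit(raw)
        feats = self.featurizer.transform(raw)
        labels = build_training_classes(
            feats, partitions, masks,
            overlap_threshold=cfg.overlap_threshold,
            n_classes=cfg.n_classes, seed=cfg.seed,
        )
        smallest = int(np.bincount(labels)[1:].min())
        n_atoms = min(cfg.n_atoms, smallest)
        if n_atoms < cfg.n_atoms:
            logger.warning(
                "n_atoms reduced from %d to %d (smallest class size)",
                cfg.n_atoms, n_atoms,
            )
        self.classifier = DictionaryClassifier(
            n_atoms=n_atoms, eps1=cfg.eps1, eps2=cfg.eps2,
            eta1=cfg.eta1, eta2=cfg.eta2, max_iter=cfg.dict_max_iter,
            tol=cfg.dict_tol, random_state=cfg.seed,
        ).fit(feats, labels)
        return self

    def classify_regions(self, image: np.ndarray):
        """Oversegment an image and label every superpixel."""
        if self.classifier is None:
            raise RuntimeError("model is not fitted")
        cfg = self.config
        partition = oversegment(image, cfg.n_superpixels, cfg.compactness)
        raw = extract_features(image, partition)
        feats = self.featurizer.transform(raw)
        labels = self.classifier.predict(feats)
        return partition, labels

    def propose(
        self, image: np.ndarray, n_perturb: int | None = None,
        seed: int | None = None,
    ) -> list[tuple[CandidateRegion, list[Anchor]]]:
        """Candidate regions with their 9 scale-adaptive anchors (+augmentation).

        All candidates proceed to anchor generation; candidates are ordered
        by descending area, so the first entry is the dominant LV
        hypothesis.
        """
        cfg = self.config
        n_perturb = cfg.n_perturb if n_perturb is None else n_perturb
        seed = cfg.seed if seed is None else seed
        partition, labels = self.classify_regions(image)
        candidates = fuse(partition, labels, lv_class=1,
                          min_area=cfg.min_candidate_area)
        s1, s2 = cfg.dict_scales
        out = []
        for k, cand in enumerate(candidates):
            sal = saliency_anchor(cand)
            aset = scale_adaptive_anchors(sal, s1, s2)
            if n_perturb:
                aset = aset + anchor_mod.perturb_anchors(
                    aset, sal, n_perturb, seed=seed + k
                )
            out.append((cand, aset))
        return out


def anchors_to_dataframe(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    for col in ANCHOR_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    return df[ANCHOR_COLUMNS]


def run_propose_dict(
    image: np.ndarray,
    model: DictionaryProposalModel,
    out_csv: str | Path | None = None,
    n_perturb: int | None = None,
    seed: int | None = None,
) -> tuple[list[tuple[CandidateRegion, list[Anchor]]], pd.DataFrame]:
    """Dictionary-path proposals for one image, optionally written as CSV."""
    proposals = model.propose(image, n_perturb=n_perturb, seed=seed)
    rows = []
    for cand, aset in proposals:
        for a in aset:
            x1, y1, x2, y2 = a.box
            rows.append(dict(frame=0, candidate=cand.region_id, x1=x1, y1=y1,
                             x2=x2, y2=y2, tag=a.tag))
    if not rows:
        logger.warning("no LV candidate region found; emitting empty CSV")
    df = anchors_to_dataframe(rows)
    if out_csv is not None:
        df.to_csv(out_csv, index=False)
    return proposals, df


def run_propose_track(
    frames: list[np.ndarray],
    seed_box: tuple[float, float, float, float],
    config: RunConfig | None = None,
    out_csv: str | Path | None = None,
) -> tuple[list[DetectionBox], pd.DataFrame]:
    """Tracker-path proposals along one individual's slice sequence.

    Frame 0 anchors come from the seed box itself; each later frame's come
    from the tracked box.  On tracking failure the partial output up to the
    failing frame is returned.
    """
    config = config or RunConfig()
    s1, s2 = config.track_scales
    rows: list[dict] = []
    boxes: list[DetectionBox] = []

    def emit(frame_idx, box, extra=None):
        sal = Anchor(cx=(box[0] + box[2]) / 2, cy=(box[1] + box[3]) / 2,
                     w=box[2] - box[0], h=box[3] - box[1], tag="saliency")
        for a in scale_adaptive_anchors(sal, s1, s2):
            x1, y1, x2, y2 = a.box
            row = dict(frame=frame_idx, candidate=0, x1=x1, y1=y1, x2=x2,
                       y2=y2, tag=a.tag)
            row.update(extra or {})
            rows.append(row)

    boxes.append(DetectionBox(*seed_box, score=1.0, image_id=0))
    emit(0, seed_box)
    state = BlockTracker(frames[0], seed_box, config.tracker_config())
    for t, frame in enumerate(frames[1:], start=1):
        try:
            det = state.step(frame)
        except TrackingError:
            logger.warning("tracking failed at frame %d; stopping", t)
            break
        boxes.append(det)
        emit(t, det.box, dict(n_star=state.last_scale_index,
                              p1_y=state.last_p1[0], p1_x=state.last_p1[1],
                              pt_y=state.center[0], pt_x=state.center[1]))
    df = anchors_to_dataframe(rows)
    if out_csv is not None:
        df.to_csv(out_csv, index=False)
    return boxes, df


# ---------------------------------------------------------------------------
# serialization and image I/O
# ---------------------------------------------------------------------------


def save_model(model: DictionaryProposalModel, path: str | Path) -> None:
    """Serialize the fitted proposer (dictionary + PCA basis) to one archive."""
    if model.classifier is None:
        raise RuntimeError("model is not fitted")
    dic = model.classifier.model_
    arrays = {
        "classes": model.classifier.classes_,
        "code_means": np.stack(dic.class_code_means),
        "pca_components": model.featurizer.pca_.components_,
        "pca_mean": model.featurizer.pca_.mean_,
        "pca_variance": model.featurizer.pca_.explained_variance_,
        "hyper": np.array([dic.eps1, dic.eps2, dic.eta1, dic.eta2]),
        "history": np.array(dic.objective_history),
    }
    if model.featurizer.standardize:
        arrays["feat_mean"] = model.featurizer.mean_
        arrays["feat_scale"] = model.featurizer.scale_
    for i, Di in enumerate(dic.sub_dictionaries):
        arrays[f"subdict_{i}"] = Di
    np.savez(path, **arrays)


def load_model(
    path: str | Path, config: RunConfig | None = None
) -> DictionaryProposalModel:
    with np.load(path, allow_pickle=False) as data:
        n_classes = sum(1 for k in data.files if k.startswith("subdict_"))
        subs = [data[f"subdict_{i}"] for i in range(n_classes)]
        eps1, eps2, eta1, eta2 = data["hyper"]
        dic = DiscriminativeDictionary(
            sub_dictionaries=subs,
            class_code_means=list(data["code_means"]),
            eps1=float(eps1), eps2=float(eps2),
            eta1=float(eta1), eta2=float(eta2),
            objective_history=list(data["history"]),
        )
        model = DictionaryProposalModel(config)
        clf = DictionaryClassifier(n_atoms=subs[0].shape[1], eps1=float(eps1),
                                   eps2=float(eps2), eta1=float(eta1),
                                   eta2=float(eta2))
        clf.classes_ = data["classes"]
        clf.model_ = dic
        clf.objective_history_ = dic.objective_history
        model.classifier = clf
        has_std = "feat_mean" in data.files
        feat = RegionFeaturizer(n_components=data["pca_components"].shape[0],
                                standardize=has_std)
        from sklearn.decomposition import PCA

        pca = PCA(n_components=data["pca_components"].shape[0])
        pca.components_ = data["pca_components"]
        pca.mean_ = data["pca_mean"]
        pca.explained_variance_ = data["pca_variance"]
        feat.pca_ = pca
        feat.n_components_ = pca.components_.shape[0]
        if has_std:
            feat.mean_ = data["feat_mean"]
            feat.scale_ = data["feat_scale"]
        model.featurizer = feat
    return model


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF as grayscale float on [0, 1]."""
    from skimage.io import imread

    img = imread(path)
    if img.ndim == 3:
        img = img.mean(axis=-1)
    img = img.astype(float)
    if img.max() > 1.0:
        img = img / 255.0
    return img


def load_frames(paths_or_nifti: list[str | Path] | str | Path) -> list[np.ndarray]:
    """Load a slice sequence from image files or slice-wise from one NIfTI."""
    if isinstance(paths_or_nifti, (str, Path)) and str(paths_or_nifti).endswith(
        (".nii", ".nii.gz")
    ):
        import nibabel as nib

        vol = np.asanyarray(nib.load(str(paths_or_nifti)).dataobj).astype(float)
        if vol.ndim != 3:
            raise ValueError("expected a 3-D NIfTI volume")
        lo, hi = vol.min(), vol.max()
        if hi > lo:
            vol = (vol - lo) / (hi - lo)
        return [vol[:, :, k] for k in range(vol.shape[2])]
    return [load_image(p) for p in list(paths_or_nifti)]
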