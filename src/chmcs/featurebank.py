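"""Feature-bank assembly: enumerate descriptor configurations and extract them.

A *representation* is the cross product of color spaces, descriptors
(cooccurrence matrices and/or opponent LBP), component pairs and parameter
settings. Its dimensionality is

    D = Nspac * sum_p Npair_p * Npara_p * Nfeat_p

with Nfeat = 13 Haralick features per cooccurrence matrix and 17 histogram
statistics per LBP pair/setting. The familiar named representations are:

======  ============  ===============  =====================
name    color spaces  settings         D (RSCCM / EOCLBP)
======  ============  ===============  =====================
SPSC    1             1                78 / 153
SPMC    5             1                390 / 765
MPSC    1             all (25 / 13)    1950 / 1989
MPMC    5             all              9750 / 9945
CHMCS   5             all, hybrid      19,695
======  ============  ===============  =====================

Feature columns follow a fixed canonical order — space-major, then
descriptor (RSCCM before EOCLBP), then component pair, then setting, then
feature name — so extractions are bit-stable across runs. Every column
carries a provenance record identifying its full configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image

from . import colorspaces, cooccurrence, lbp
from .colorspaces import SPACES
from .cooccurrence import HARALICK_NAMES, RSCCM_PAIRS, RSCCM_SETTINGS
from .lbp import LBP_PAIRS, LBP_SETTINGS, STAT17_NAMES

__all__ = [
    "RepresentationSpec",
    "FeatureProvenance",
    "FeatureBank",
    "dimensionality",
    "enumerate_provenance",
    "extract_image",
    "extract_dataset",
    "load_image",
    "full_chmcs_spec",
    "spsc_spec",
    "mpmc_spec",
]


@dataclass(frozen=True)
class RepresentationSpec:
    """Which color spaces, descriptors and settings make up a representation."""

    spaces: tuple[str, ...] = SPACES
    use_rsccm: bool = True
    use_eoclbp: bool = True
    rsccm_settings: tuple[tuple[int, int], ...] = RSCCM_SETTINGS
    eoclbp_settings: tuple[tuple[int, int], ...] = LBP_SETTINGS

    def __post_init__(self):
        if not self.spaces:
            raise ValueError("at least one color space is required")
        for s in self.spaces:
            if s not in SPACES:
                raise ValueError(f"unknown color space {s!r}")
        if len(set(self.spaces)) != len(self.spaces):
            raise ValueError("duplicate color spaces in spec")
        if not (self.use_rsccm or self.use_eoclbp):
            raise ValueError("at least one descriptor must be enabled")
        if self.use_rsccm:
            if not self.rsccm_settings:
                raise ValueError("RSCCM enabled but no (delta, Q) settings given")
            for st in self.rsccm_settings:
                if tuple(st) not in RSCCM_SETTINGS:
                    raise ValueError(f"RSCCM setting {st} is not in the 25-setting grid")
        if self.use_eoclbp:
            if not self.eoclbp_settings:
                raise ValueError("EOCLBP enabled but no (P, delta) settings given")
            for st in self.eoclbp_settings:
                if tuple(st) not in LBP_SETTINGS:
                    raise ValueError(f"EOCLBP setting {st} is not in the 13-setting list")

    @property
    def delta_max(self) -> int:
        deltas = []
        if self.use_rsccm:
            deltas += [d for d, _ in self.rsccm_settings]
        if self.use_eoclbp:
            deltas += [d for _, d in self.eoclbp_settings]
        return max(deltas)

    def to_dict(self) -> dict:
        return {
            "spaces": list(self.spaces),
            "use_rsccm": self.use_rsccm,
            "use_eoclbp": self.use_eoclbp,
            "rsccm_settings": [list(s) for s in self.rsccm_settings],
            "eoclbp_settings": [list(s) for s in self.eoclbp_settings],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RepresentationSpec":
        return cls(
            spaces=tuple(d.get("spaces", SPACES)),
            use_rsccm=bool(d.get("use_rsccm", True)),
            use_eoclbp=bool(d.get("use_eoclbp", True)),
            rsccm_settings=tuple(tuple(s) for s in d.get("rsccm_settings", RSCCM_SETTINGS)),
            eoclbp_settings=tuple(tuple(s) for s in d.get("eoclbp_settings", LBP_SETTINGS)),
        )


def full_chmcs_spec() -> RepresentationSpec:
    """All 5 spaces, both descriptors, all settings: D = 19,695."""
    return RepresentationSpec()


def spsc_spec(space: str, descriptor: str, setting: tuple[int, int]) -> RepresentationSpec:
    """Single parameter setting, single color space (one descriptor)."""
    if descriptor == "RSCCM":
        return RepresentationSpec(spaces=(space,), use_rsccm=True, use_eoclbp=False,
                                  rsccm_settings=(tuple(setting),))
    if descriptor == "EOCLBP":
        return RepresentationSpec(spaces=(space,), use_rsccm=False, use_eoclbp=True,
                                  eoclbp_settings=(tuple(setting),))
    raise ValueError(f"unknown descriptor {descriptor!r}")


def mpmc_spec(descriptor: str) -> RepresentationSpec:
    """Multiple settings, multiple color spaces, one descriptor."""
    if descriptor == "RSCCM":
        return RepresentationSpec(use_rsccm=True, use_eoclbp=False)
    if descriptor == "EOCLBP":
        return RepresentationSpec(use_rsccm=False, use_eoclbp=True)
    raise ValueError(f"unknown descriptor {descriptor!r}")


@dataclass(frozen=True)
class FeatureProvenance:
    """Full configuration of one feature column."""

    descriptor: str  # "RSCCM" | "EOCLBP"
    space: str
    pair: tuple[int, int]
    setting: tuple[int, int]
    feature: str
    index: int

    @property
    def name(self) -> str:
        g, gp = self.pair
        if self.descriptor == "RSCCM":
            d, q = self.setting
            return f"RSCCM|{self.space}|C{g}C{gp}|d{d}q{q}|{self.feature}"
        p, d = self.setting
        return f"EOCLBP|{self.space}|C{g}C{gp}|p{p}d{d}|{self.feature}"

    @classmethod
    def from_name(cls, name: str, index: int) -> "FeatureProvenance":
        desc, space, pair_s, setting_s, feat = name.split("|")
        pair = (int(pair_s[1]), int(pair_s[3]))
        if desc == "RSCCM":
            d, q = setting_s[1:].split("q")
            setting = (int(d), int(q))
        else:
            p, d = setting_s[1:].split("d")
            setting = (int(p), int(d))
        return cls(desc, space, pair, setting, feat, index)


def dimensionality(spec: RepresentationSpec) -> int:
    """Total column count of a representation."""
    per_space = 0
    if spec.use_rsccm:
        per_space += len(RSCCM_PAIRS) * len(spec.rsccm_settings) * len(HARALICK_NAMES)
    if spec.use_eoclbp:
        per_space += len(LBP_PAIRS) * len(spec.eoclbp_settings) * len(STAT17_NAMES)
    return len(spec.spaces) * per_space


def enumerate_provenance(spec: RepresentationSpec) -> list[FeatureProvenance]:
    """Provenance records in canonical (space, descriptor, pair, setting, feature) order."""
    records: list[FeatureProvenance] = []
    idx = 0
    for space in spec.spaces:
        if spec.use_rsccm:
            for pair in RSCCM_PAIRS:
                for setting in spec.rsccm_settings:
                    for feat in HARALICK_NAMES:
                        records.append(FeatureProvenance("RSCCM", space, pair, setting, feat, idx))
                        idx += 1
        if spec.use_eoclbp:
            for pair in LBP_PAIRS:
                for setting in spec.eoclbp_settings:
                    for feat in STAT17_NAMES:
                        records.append(FeatureProvenance("EOCLBP", space, pair, setting, feat, idx))
                        idx += 1
    return records


def _check_image_size(image: np.ndarray, spec: RepresentationSpec) -> None:
    h, w = image.shape[0], image.shape[1]
    if spec.use_rsccm:
        for d, q in spec.rsccm_settings:
            if min(h, w) < 2 * d + 1:
                raise ValueError(
                    f"image {h}x{w} is too small for RSCCM setting (delta={d}, Q={q}); "
                    f"at least {2 * d + 1} pixels per side are required"
                )
    if spec.use_eoclbp:
        for p, d in spec.eoclbp_settings:
            if min(h, w) < 2 * d + 1:
                raise ValueError(
                    f"image {h}x{w} is too small for EOCLBP setting (P={p}, delta={d}); "
                    f"at least {2 * d + 1} pixels per side are required"
                )


def extract_image(image: np.ndarray, spec: RepresentationSpec) -> np.ndarray:
    """Extract the full feature vector of one RGB image, in canonical order."""
    image = np.asarray(image)
    _check_image_size(image, spec)
    chunks: list[np.ndarray] = []
    for space in spec.spaces:
        planes = colorspaces.convert(image, space)
        if spec.use_rsccm:
            # quantized planes are shared across pairs for each Q
            quant: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
            for _, q in spec.rsccm_settings:
                if q not in quant:
                    quant[q] = tuple(
                        cooccurrence.quantize_channel(planes.channel(g), q) for g in (1, 2, 3)
                    )
            for g, gp in RSCCM_PAIRS:
                for setting in spec.rsccm_settings:
                    planes_q = quant[setting[1]]
                    m = cooccurrence.compute_rsccm(
                        planes_q[g - 1], planes_q[gp - 1], setting, pair=(g, gp)
                    )
                    chunks.append(cooccurrence.haralick13(m))
        if spec.use_eoclbp:
            for g, gp in LBP_PAIRS:
                for setting in spec.eoclbp_settings:
                    codes = lbp.compute_lbp(planes.channel(g), planes.channel(gp), setting)
                    chunks.append(lbp.stats17(lbp.lbp_histogram(codes)))
    vector = np.concatenate(chunks)
    assert vector.size == dimensionality(spec)
    return vector


def load_image(path: str) -> np.ndarray:
    """Read an 8-bit RGB image (PNG/TIFF/BMP). Alpha is dropped, grayscale rejected."""
    with Image.open(path) as im:
        if im.mode in ("L", "I", "I;16", "1", "F"):
            raise ValueError(f"{path}: grayscale images are not supported")
        if im.mode == "P":
            im = im.convert("RGB")
        arr = np.asarray(im)
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a color image, got shape {arr.shape}")
    return arr[:, :, :3]


@dataclass
class FeatureBank:
    """Sample x feature matrix with labels, split tags and column provenance."""

    X: np.ndarray
    labels: np.ndarray
    provenance: list[FeatureProvenance]
    splits: np.ndarray | None = None
    spec: RepresentationSpec | None = None
    paths: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.X.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if self.X.shape[0] != self.labels.shape[0]:
            raise ValueError("one label per sample is required")
        if np.isnan(self.X).any():
            raise ValueError("feature matrix contains missing values")
        if len(self.provenance) != self.X.shape[1]:
            raise ValueError("one provenance record per column is required")
        if self.splits is not None:
            self.splits = np.asarray(self.splits)
            if self.splits.shape[0] != self.X.shape[0]:
                raise ValueError("one split tag per sample is required")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def feature_names(self) -> list[str]:
        return [p.name for p in self.provenance]

    def rows(self, split: str) -> "FeatureBank":
        """Sub-bank restricted to one split ('train' or 'test')."""
        if self.splits is None:
            raise ValueError("this bank carries no train/test split")
        mask = self.splits == split
        return FeatureBank(self.X[mask], self.labels[mask], self.provenance,
                           splits=self.splits[mask], spec=self.spec,
                           paths=[p for p, m in zip(self.paths, mask) if m] if self.paths else [])

    def select_columns(self, indices) -> "FeatureBank":
        indices = list(indices)
        prov = [FeatureProvenance(self.provenance[j].descriptor, self.provenance[j].space,
                                  self.provenance[j].pair, self.provenance[j].setting,
                                  self.provenance[j].feature, k)
                for k, j in enumerate(indices)]
        return FeatureBank(self.X[:, indices], self.labels, prov, splits=self.splits,
                           spec=None, paths=self.paths)

    @classmethod
    def from_matrix(cls, X, labels, splits=None, names=None) -> "FeatureBank":
        """Bank from a plain matrix (selection-only path); generic provenance."""
        X = np.asarray(X, dtype=np.float64)
        if names is None:
            names = [f"F{k}" for k in range(X.shape[1])]
        prov = []
        for k, name in enumerate(names):
            if "|" in name:
                prov.append(FeatureProvenance.from_name(name, k))
            else:
                prov.append(FeatureProvenance("RAW", "-", (0, 0), (0, 0), name, k))
        return cls(X, labels, prov, splits=splits)

    def to_csv(self, path: str) -> None:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df.insert(0, "label", self.labels)
        df.insert(1, "split", self.splits if self.splits is not None else "train")
        df.to_csv(path, index=False)
        if self.spec is not None:
            with open(str(path) + ".spec.json", "w") as fh:
                json.dump(self.spec.to_dict(), fh, indent=2)

    @classmethod
    def from_csv(cls, path: str) -> "FeatureBank":
        df = pd.read_csv(path)
        for col in ("label", "split"):
            if col not in df.columns:
                raise ValueError(f"{path}: missing required column {col!r}")
        names = [c for c in df.columns if c not in ("label", "split")]
        raw = any("|" not in c for c in names)
        X = df[names].to_numpy(dtype=np.float64)
        bank = cls.from_matrix(X, df["label"].to_numpy(), splits=df["split"].to_numpy(),
                               names=None if raw else names)
        if raw:
            bank.provenance = [FeatureProvenance("RAW", "-", (0, 0), (0, 0), n, k)
                               for k, n in enumerate(names)]
        return bank


def extract_dataset(manifest, spec: RepresentationSpec, root: str | None = None) -> FeatureBank:
    """Extract a FeatureBank from a manifest (CSV path or DataFrame).

    The manifest must have columns ``path,label,split``; rows are processed
    in manifest order.
    """
    import os

    if isinstance(manifest, (str, bytes)) or hasattr(manifest, "__fspath__"):
        df = pd.read_csv(manifest)
        if root is None:
            root = os.path.dirname(str(manifest))
    else:
        df = manifest.copy()
    for col in ("path", "label", "split"):
        if col not in df.columns:
            raise ValueError(f"manifest is missing required column {col!r}")
    if len(df) == 0:
        raise ValueError("manifest contains no rows")
    if df["label"].isna().any():
        raise ValueError("manifest contains rows with a missing label")

    rows = []
    paths = []
    for _, rec in df.iterrows():
        p = rec["path"]
        full = os.path.join(root, p) if root and not os.path.isabs(str(p)) else str(p)
        try:
            img = load_image(full)
        except (OSError, FileNotFoundError) as exc:
            raise ValueError(f"cannot read image {full!r}: {exc}") from exc
        rows.append(extract_image(img, spec))
        paths.append(full)
    X = np.vstack(rows)
    return FeatureBank(X, df["label"].to_numpy(), enumerate_provenance(spec),
                       splits=df["split"].to_numpy(), spec=spec, paths=paths)
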