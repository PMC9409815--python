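"""Synthetic color textures and planted feature banks.

Two generators make every pipeline stage testable without any benchmark
download:

* :func:`make_texture_dataset` renders class-structured color textures.
  Each class is an oriented sinusoidal field plus a second, orthogonal
  component and a noise field, mixed across the three channels by a
  class-specific matrix. Classes therefore differ in spatial frequency,
  orientation and inter-channel correlation — exactly the properties that
  cooccurrence matrices and opponent LBP codes measure — while per-image
  phase, orientation/frequency jitter and pixel noise create realistic
  within-class variation.

* :func:`make_planted_bank` draws a feature matrix with a known ground
  truth: informative columns whose class means are separated, near-duplicate
  redundant copies of each informative column (correlated above 0.95 by
  construction), and label-independent noise columns. This exercises the
  clustering and selection stages against a known answer.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from PIL import Image

from .featurebank import FeatureBank, FeatureProvenance

__all__ = [
    "TextureRecipe",
    "PlantedBankRecipe",
    "class_recipes",
    "render_texture",
    "make_texture_dataset",
    "make_planted_bank",
]


@dataclass(frozen=True)
class TextureRecipe:
    """Rendering parameters of one texture class."""

    class_id: int
    frequency: float  # cycles per pixel of the main sinusoid
    orientation: float  # radians
    mixing: tuple  # 3 x 3 channel mixing matrix (rows -> channels)
    noise_level: float = 2.0  # sd of additive per-channel noise, in signal units
    freq_jitter: float = 0.12  # relative per-image frequency variation
    orient_jitter: float = 0.35  # per-image orientation variation (rad, ~20 deg)

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "TextureRecipe":
        d = json.loads(s)
        d["mixing"] = tuple(tuple(row) for row in d["mixing"])
        return cls(**d)


def class_recipes(n_classes: int, seed: int) -> list[TextureRecipe]:
    """Deterministic per-class recipes: spread orientations and frequencies,
    class-specific channel mixing drawn from the seed."""
    rng = np.random.default_rng(seed)
    recipes = []
    for k in range(n_classes):
        # Adjacent classes differ subtly in frequency; within-class jitter and
        # noise (TextureRecipe defaults) keep any single descriptor
        # configuration far from perfect, which is the regime where combining
        # configurations matters.
        freq = 0.08 + 0.012 * k
        theta = np.pi * k / max(n_classes, 1)
        mix = rng.uniform(-1.0, 1.0, size=(3, 3))
        mix /= np.abs(mix).sum(axis=1, keepdims=True)  # keep channels in range
        recipes.append(TextureRecipe(
            class_id=k,
            frequency=float(freq),
            orientation=float(theta),
            mixing=tuple(tuple(float(v) for v in row) for row in mix),
        ))
    return recipes


def render_texture(recipe: TextureRecipe, size: int, rng: np.random.Generator) -> np.ndarray:
    """Render one H x W x 3 uint8 texture image from a class recipe.

    The per-image random state (phases, jitter, noise) comes from ``rng``.
    """
    f = recipe.frequency * (1.0 + recipe.freq_jitter * rng.standard_normal())
    theta = recipe.orientation + recipe.orient_jitter * rng.standard_normal()
    phase1, phase2 = rng.uniform(0.0, 2.0 * np.pi, size=2)
    rr, cc = np.mgrid[0:size, 0:size].astype(np.float64)
    u = np.cos(theta) * cc + np.sin(theta) * rr
    v = -np.sin(theta) * cc + np.cos(theta) * rr
    s1 = np.sin(2.0 * np.pi * f * u + phase1)
    s2 = np.sin(2.0 * np.pi * (1.7 * f) * v + phase2)
    nfield = 0.5 * rng.standard_normal((size, size))
    base = np.stack([s1, s2, nfield])  # 3 x H x W
    mix = np.asarray(recipe.mixing)
    chans = np.tensordot(mix, base, axes=1)
    chans += recipe.noise_level * rng.standard_normal(chans.shape)
    img = 127.5 + 110.0 * chans
    return np.clip(np.rint(img), 0, 255).astype(np.uint8).transpose(1, 2, 0)


def make_texture_dataset(
    n_classes: int,
    n_per_class: int,
    size: int = 64,
    seed: int = 0,
    out_dir: str | None = None,
):
    """Generate a labeled, split texture dataset.

    Returns ``(images, labels, manifest)`` where ``manifest`` is a DataFrame
    with columns ``path,label,split``; the first half of each class is tagged
    ``train`` and the second half ``test``. With ``out_dir`` the images are
    also written as PNG together with ``manifest.csv``.
    """
    if n_classes < 1 or n_per_class < 1:
        raise ValueError("n_classes and n_per_class must be at least 1")
    if size < 3:
        raise ValueError("size must be at least 3 pixels")
    recipes = class_recipes(n_classes, seed)
    rng = np.random.default_rng(seed + 1)
    images, labels, rows = [], [], []
    for recipe in recipes:
        for i in range(n_per_class):
            img = render_texture(recipe, size, rng)
            label = f"class{recipe.class_id}"
            split = "train" if i < n_per_class // 2 or n_per_class == 1 else "test"
            path = f"{label}_{i:03d}.png"
            images.append(img)
            labels.append(label)
            rows.append({"path": path, "label": label, "split": split})
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        for img, row in zip(images, rows):
            Image.fromarray(img).save(os.path.join(out_dir, row["path"]))
        manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return images, np.array(labels), manifest


@dataclass(frozen=True)
class PlantedBankRecipe:
    """Parameters of a feature bank with known informative structure."""

    n_samples: int = 60
    n_classes: int = 3
    n_informative: int = 6
    class_separation: float = 2.0  # distance between adjacent class means, in sd units
    n_copies: int = 4  # redundant near-duplicates per informative feature
    n_noise: int = 90  # label-independent features
    copy_noise: float = 0.1  # sd of the perturbation on each redundant copy
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "PlantedBankRecipe":
        return cls(**json.loads(s))

    @property
    def n_features(self) -> int:
        return self.n_informative * (1 + self.n_copies) + self.n_noise


def make_planted_bank(recipe: PlantedBankRecipe):
    """Draw a planted feature bank and its ground-truth column partition.

    Returns ``(bank, truth)`` where ``truth`` maps ``"informative"``,
    ``"redundant"`` and ``"noise"`` to sorted column-index lists, and
    ``"informative_block"`` to the union of informative and redundant
    columns. A redundant copy is its informative parent plus N(0, copy_noise)
    noise, so the parent/copy correlation is about
    ``1 / sqrt(1 + copy_noise^2)`` (> 0.995 at the default 0.1).
    """
    r = recipe
    rng = np.random.default_rng(r.seed)
    n_per = r.n_samples // r.n_classes
    if n_per < 1:
        raise ValueError("need at least one sample per class")
    y = np.repeat([f"class{j}" for j in range(r.n_classes)],
                  [n_per + (1 if j < r.n_samples % r.n_classes else 0)
                   for j in range(r.n_classes)])

    cols, kinds = [], []
    # Informative features: class-shifted unit-variance Gaussians. Each
    # feature gets its own random permutation of the class-mean ladder so
    # different informative features discriminate along different axes.
    informative_cols = []
    for _ in range(r.n_informative):
        means = r.class_separation * rng.permutation(np.arange(r.n_classes, dtype=float))
        centers = means[[int(lbl[5:]) for lbl in y]]
        col = centers + rng.standard_normal(len(y))
        informative_cols.append(col)
        cols.append(col)
        kinds.append("informative")
        for _ in range(r.n_copies):
            cols.append(col + r.copy_noise * rng.standard_normal(len(y)))
            kinds.append("redundant")
    for _ in range(r.n_noise):
        cols.append(rng.standard_normal(len(y)))
        kinds.append("noise")

    X = np.column_stack(cols)
    names = [f"{kind}_{k}" for k, kind in enumerate(kinds)]
    prov = [FeatureProvenance("RAW", "-", (0, 0), (0, 0), n, k) for k, n in enumerate(names)]
    bank = FeatureBank(X, y, prov)
    truth = {
        "informative": [k for k, kd in enumerate(kinds) if kd == "informative"],
        "redundant": [k for k, kd in enumerate(kinds) if kd == "redundant"],
        "noise": [k for k, kd in enumerate(kinds) if kd == "noise"],
    }
    truth["informative_block"] = sorted(truth["informative"] + truth["redundant"])
    return bank, truth
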