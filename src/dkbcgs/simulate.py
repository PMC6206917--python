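"""Seeded synthetic expression datasets with known informative-gene ground truth.

The generator emulates the microarray benchmark regime the selection method
targets: few samples (tens), many genes (thousands), 2-5 classes, and a small
planted set of class-informative genes on a Gaussian noise background.

Generative model (per gene g, class i, sample j in class i):

    x = b_g + mu_{g,i} + Normal(0, noise_sd^2)

where b_g ~ Normal(0, baseline_sd^2) is a gene-specific baseline, and the
class shift mu_{g,i} is zero for uninformative genes and
``effect_size * noise_sd * s_i`` for informative ones, with the class scores
s_i equally spaced in [-1, 1] — so a two-class problem has a between-class
mean gap of ``2 * effect_size * noise_sd``, and multiclass problems have
ordered, symmetric structure.  Everything is a deterministic function of the
seed.

Deliberately not modeled: gene-gene covariance, batch effects, heavy tails,
count noise — the generator validates the machinery, not real-data
performance.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .data_io import ExpressionDataset

__all__ = ["SyntheticSpec", "generate", "paper_regime_presets"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic dataset.

    ``effect_size`` is the class mean-shift scale in units of ``noise_sd``;
    ``class_proportions`` defaults to uniform.
    """

    n_samples: int = 40
    n_genes: int = 1519
    n_classes: int = 2
    class_proportions: tuple | None = None
    n_informative: int = 20
    effect_size: float = 2.0
    noise_sd: float = 1.0
    baseline_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 4:
            raise ValueError(f"n_samples must be >= 4, got {self.n_samples}")
        if self.n_genes < 2:
            raise ValueError(f"n_genes must be >= 2, got {self.n_genes}")
        if self.n_classes < 2:
            raise ValueError(f"n_classes must be >= 2, got {self.n_classes}")
        if not (0 <= self.n_informative <= self.n_genes):
            raise ValueError(
                f"n_informative must be in [0, {self.n_genes}], got {self.n_informative}"
            )
        if not (self.effect_size >= 0):
            raise ValueError(f"effect_size must be >= 0, got {self.effect_size}")
        if not (self.noise_sd > 0):
            raise ValueError(f"noise_sd must be > 0, got {self.noise_sd}")
        if not (self.baseline_sd >= 0):
            raise ValueError(f"baseline_sd must be >= 0, got {self.baseline_sd}")
        if self.class_proportions is not None:
            p = np.asarray(self.class_proportions, dtype=float)
            if p.size != self.n_classes or np.any(p <= 0) or abs(p.sum() - 1) > 1e-9:
                raise ValueError(
                    "class_proportions must be a positive vector of length "
                    f"{self.n_classes} summing to 1"
                )


def _class_counts(spec: SyntheticSpec) -> np.ndarray:
    """Largest-remainder apportionment of n_samples to the class proportions."""
    p = (
        np.full(spec.n_classes, 1.0 / spec.n_classes)
        if spec.class_proportions is None
        else np.asarray(spec.class_proportions, dtype=float)
    )
    exact = p * spec.n_samples
    counts = np.floor(exact).astype(int)
    rem = spec.n_samples - counts.sum()
    order = np.argsort(-(exact - counts), kind="stable")
    counts[order[:rem]] += 1
    if np.any(counts < 1):
        raise ValueError("every class needs at least 1 sample; adjust proportions")
    return counts


def generate(spec: SyntheticSpec) -> tuple[ExpressionDataset, np.ndarray]:
    """Generate one dataset; returns it with the true informative gene indices."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    counts = _class_counts(spec)

    labels = np.concatenate(
        [np.repeat(f"class{i}", c) for i, c in enumerate(counts)]
    )
    rng.shuffle(labels)

    informative = np.sort(
        rng.choice(spec.n_genes, size=spec.n_informative, replace=False)
    )
    baseline = rng.normal(0.0, spec.baseline_sd, size=spec.n_genes)

    # class scores equally spaced in [-1, 1]
    scores = (
        np.linspace(-1.0, 1.0, spec.n_classes)
        if spec.n_classes > 1
        else np.zeros(1)
    )
    shifts = np.zeros((spec.n_classes, spec.n_genes))
    shifts[:, informative] = (
        spec.effect_size * spec.noise_sd * scores[:, None]
    )

    class_idx = np.array([int(lab[5:]) for lab in labels])
    values = (
        baseline[None, :]
        + shifts[class_idx]
        + rng.normal(0.0, spec.noise_sd, size=(spec.n_samples, spec.n_genes))
    )

    width = len(str(spec.n_samples - 1))
    gwidth = len(str(spec.n_genes - 1))
    ds = ExpressionDataset(
        values,
        [f"s{i:0{width}d}" for i in range(spec.n_samples)],
        [f"g{j:0{gwidth}d}" for j in range(spec.n_genes)],
        labels,
    )
    return ds, informative


def paper_regime_presets() -> dict[str, SyntheticSpec]:
    """Presets mirroring the benchmark dataset shapes (n, classes, genes).

    All use 20 informative genes, effect size 2 and unit noise by default;
    override with :func:`dataclasses.replace`.
    """
    shapes = {
        "dlbcl-like": (77, 2, 7129),
        "gastric-like": (40, 2, 1519),
        "multicancer-like": (152, 5, 65522),
        "lymphoma-like": (62, 3, 4026),
    }
    return {
        name: SyntheticSpec(n_samples=n, n_classes=c, n_genes=l)
        for name, (n, c, l) in shapes.items()
    }


def preset(name: str, **overrides) -> SyntheticSpec:
    """Look up a preset by name, optionally overriding fields."""
    presets = paper_regime_presets()
    if name not in presets:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(presets)}")
    return replace(presets[name], **overrides)
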