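"""The published seven-descriptor BRD-4 model as a fixed predictor.

The regression was trained on 785 curated BRD-4 inhibitors:

    pIC50 = 4.27 + 0.093 fsp3CringC2B + 0.108 com_C_4A
          + 0.391 Saturated_Carbo_Rings + 0.428 fsulfonSaroC8B
          + 0.625 flipoacc3B + 0.921 fsp3OaroN6B - 0.367 fplaNN4B

Coefficients, standard errors and the warning leverage h* = 0.031 are
loaded from a versioned asset file and never re-fitted here.  The only
geometry-dependent descriptor is ``com_C_4A``; because the original
training geometries came from semi-empirical (PM3) optimisation, which
this package does not reproduce, predictions from re-embedded
distance-geometry conformers are labelled with their geometry source
and should be treated as approximate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import numpy as np

from .curation import MoleculeRecord, embed3d
from .descriptors import DescriptorError, model_a_descriptors


@dataclass(frozen=True)
class ModelA:
    """Immutable packaged regression model."""

    intercept: float
    coefficients: dict[str, float]  # ordered as published
    coefficient_se: dict[str, float]
    intercept_se: float
    n_training: int
    h_star: float
    training_statistics: dict[str, float]

    @property
    def descriptor_names(self) -> tuple[str, ...]:
        return tuple(self.coefficients)

    def predict(self, descriptors: Mapping[str, float]) -> float:
        """Evaluate the published equation on a named 7-vector.

        The vector must contain exactly the model's descriptor names.
        """
        expected = set(self.coefficients)
        got = set(descriptors)
        if got != expected:
            missing = sorted(expected - got)
            extra = sorted(got - expected)
            raise KeyError(
                f"descriptor vector mismatch: missing {missing}, unexpected {extra}"
            )
        return self.intercept + sum(
            self.coefficients[name] * float(descriptors[name])
            for name in self.coefficients
        )


@dataclass
class Prediction:
    """A model evaluation on one molecule, with provenance."""

    id: str
    pic50_pred: float
    descriptors: dict[str, float]
    geometry_source: str  # "sdf" or "embedded"

    @property
    def approximate_geometry(self) -> bool:
        return self.geometry_source != "sdf"


def load_model_a() -> ModelA:
    """Load the packaged model from its asset file."""
    with resources.files("brd4qsar.assets").joinpath("model_a.json").open() as fh:
        raw = json.load(fh)
    return ModelA(
        intercept=float(raw["intercept"]),
        coefficients={k: float(v) for k, v in raw["coefficients"].items()},
        coefficient_se={k: float(v) for k, v in raw["coefficient_se"].items()},
        intercept_se=float(raw["intercept_se"]),
        n_training=int(raw["n_training"]),
        h_star=float(raw["h_star"]),
        training_statistics=dict(raw["training_statistics"]),
    )


def predict_molecule(
    record: MoleculeRecord, seed: int = 42, model: ModelA | None = None
) -> Prediction:
    """Featurize one molecule and evaluate the packaged model on it.

    Embeds a seeded 3D conformer when the record carries none (needed
    for ``com_C_4A``); user-supplied SDF coordinates take precedence.
    """
    if model is None:
        model = load_model_a()
    if record.mol is None:
        raise DescriptorError(f"molecule {record.id!r}: unparseable structure")
    if not record.has_coords:
        record = embed3d(record, seed=seed)
        if not record.has_coords:
            raise DescriptorError(f"molecule {record.id!r}: 3D embedding failed")
    vector = model_a_descriptors(record)
    if any(v < 0 for k, v in vector.items()):
        raise DescriptorError(f"molecule {record.id!r}: negative descriptor count")
    return Prediction(
        id=record.id,
        pic50_pred=model.predict(vector),
        descriptors=vector,
        geometry_source=record.geometry_source or "sdf",
    )
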