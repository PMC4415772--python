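"""Concrete ionic models and the model registry."""

from .base import IonicModel, ModelState, SimulationSettings, SolverError

_REGISTRY = {}


def register(cls):
    _REGISTRY[cls.name] = cls
    return cls


def get_model(name: str) -> IonicModel:
    """Instantiate a registered model by name ('faber-rudy' or 'reduced')."""
    try:
        return _REGISTRY[name]()
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; available: {sorted(_REGISTRY)}"
        ) from None


def available_models():
    return sorted(_REGISTRY)


from .reduced import ReducedModel  # noqa: E402
from .faber_rudy import FaberRudyModel  # noqa: E402

register(ReducedModel)
register(FaberRudyModel)

__all__ = [
    "IonicModel", "ModelState", "SimulationSettings", "SolverError",
    "ReducedModel", "FaberRudyModel", "get_model", "available_models",
]
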