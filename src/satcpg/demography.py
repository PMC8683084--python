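"""Piecewise demographic histories.

A :class:`DemographicModel` is an ordered sequence of :class:`Epoch` objects
tiling the interval from ``T_model`` generations before present down to the
present (generation 0), preceded by a constant-size burn-in segment of
``burn_in_multiplier * N_ancestral`` generations. Within an epoch the diploid
effective size follows ``N_start * exp(growth_rate * (t_start - g))``, so a
positive ``growth_rate`` means the population grows toward the present.

Presets are stylized piecewise-constant approximations of a European and a
West-African size trajectory; the exact published MSMC step function can be
substituted via ``override_table`` or a user YAML/JSON model file.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

__all__ = [
    "Epoch",
    "DemographicModel",
    "PRESET_NAMES",
    "build_preset",
    "size_at",
    "load_model",
    "save_model",
    "model_from_dict",
    "model_to_dict",
]

#: per-generation rate equivalent to "4.5 % exponential growth"
GROWTH_4P5 = math.log(1.045)

PRESET_NAMES = (
    "eur_recent10M",
    "eur_recent100M",
    "eur_expgrowth",
    "yri_recent10M",
    "constant",
)


@dataclass(frozen=True)
class Epoch:
    """One demographic epoch on ``[t_end, t_start)`` generations before present.

    Parameters
    ----------
    t_start : float
        Older (inclusive) bound, generations before present.
    t_end : float
        Younger (exclusive) bound, ``>= 0``.
    N_start : float
        Diploid effective size at ``t_start``.
    growth_rate : float
        Per-generation exponential rate; 0 for a constant-size epoch.
    """

    t_start: float
    t_end: float
    N_start: float
    growth_rate: float = 0.0

    def __post_init__(self) -> None:
        if not self.t_start > self.t_end >= 0:
            raise ValueError(
                f"epoch requires t_start > t_end >= 0, got ({self.t_start}, {self.t_end})"
            )
        if self.N_start < 1:
            raise ValueError(f"N_start must be >= 1, got {self.N_start}")

    def size_at(self, g: float) -> float:
        """Diploid size at generation ``g`` before present (no bounds check)."""
        if self.growth_rate == 0.0:
            return self.N_start
        return self.N_start * math.exp(self.growth_rate * (self.t_start - g))


@dataclass(frozen=True)
class DemographicModel:
    """Piecewise-exponential demographic history with a burn-in convention.

    ``epochs`` are ordered past to present and must tile ``[0, T_model)``
    without gaps; the youngest epoch ends at generation 0. Before the oldest
    epoch the size is ``N_ancestral``, and forward simulations prepend a
    neutral burn-in of ``burn_in_multiplier * N_ancestral`` generations at
    that size.
    """

    epochs: tuple[Epoch, ...]
    N_ancestral: float
    burn_in_multiplier: float = 10.0
    name: str = ""

    def __post_init__(self) -> None:
        eps = tuple(self.epochs)
        object.__setattr__(self, "epochs", eps)
        if self.N_ancestral < 1:
            raise ValueError("N_ancestral must be >= 1")
        if self.burn_in_multiplier < 0:
            raise ValueError("burn_in_multiplier must be >= 0")
        if eps:
            if eps[-1].t_end != 0:
                raise ValueError("youngest epoch must end at generation 0")
            for older, younger in zip(eps, eps[1:]):
                if older.t_end != younger.t_start:
                    raise ValueError(
                        "epochs must tile time with no gaps or overlaps "
                        f"({older.t_end} != {younger.t_start})"
                    )

    @property
    def span(self) -> float:
        """Total modelled time excluding burn-in, in generations."""
        return self.epochs[0].t_start if self.epochs else 0.0

    @property
    def burn_in_generations(self) -> int:
        return int(round(self.burn_in_multiplier * self.N_ancestral))

    def size_at(self, g: float) -> float:
        """Diploid effective size ``g`` generations before present."""
        if g < 0:
            raise ValueError(f"generation must be >= 0, got {g}")
        if not self.epochs or g >= self.span:
            return self.N_ancestral
        for ep in self.epochs:
            if ep.t_end <= g < ep.t_start:
                return ep.size_at(g)
        # g can only fall through on floating-point edge cases; use youngest
        return self.epochs[-1].size_at(g)

    def generation_sizes(self, include_burn_in: bool = True) -> np.ndarray:
        """Integer diploid sizes, one per generation, ordered past -> present.

        Used by the forward simulator: entry ``t`` is the size of the
        generation ``span - 1 - t`` before present (so the last entry is the
        present-day size), preceded by the burn-in segment at ``N_ancestral``.
        Sizes are rounded and clamped to at least one individual.
        """
        span = int(round(self.span))
        sizes = np.empty(span, dtype=np.int64)
        for t in range(span):
            g = span - 1 - t
            sizes[t] = max(1, int(round(self.size_at(g))))
        if include_burn_in:
            burn = np.full(self.burn_in_generations, max(1, int(round(self.N_ancestral))),
                           dtype=np.int64)
            sizes = np.concatenate([burn, sizes])
        return sizes


def size_at(model: DemographicModel, g: float) -> float:
    """Module-level alias for :meth:`DemographicModel.size_at`."""
    return model.size_at(g)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def model_to_dict(model: DemographicModel) -> dict:
    return {
        "name": model.name,
        "N_ancestral": model.N_ancestral,
        "burn_in_multiplier": model.burn_in_multiplier,
        "epochs": [
            {
                "t_start": ep.t_start,
                "t_end": ep.t_end,
                "N_start": ep.N_start,
                "growth_rate": ep.growth_rate,
            }
            for ep in model.epochs
        ],
    }


def model_from_dict(d: dict) -> DemographicModel:
    epochs = tuple(
        Epoch(
            t_start=float(e["t_start"]),
            t_end=float(e["t_end"]),
            N_start=float(e["N_start"]),
            growth_rate=float(e.get("growth_rate", 0.0)),
        )
        for e in d.get("epochs", [])
    )
    return DemographicModel(
        epochs=epochs,
        N_ancestral=float(d["N_ancestral"]),
        burn_in_multiplier=float(d.get("burn_in_multiplier", 10.0)),
        name=str(d.get("name", "")),
    )


def save_model(model: DemographicModel, path: str | Path) -> None:
    path = Path(path)
    d = model_to_dict(model)
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2))
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))


def load_model(path: str | Path) -> DemographicModel:
    path = Path(path)
    text = path.read_text()
    d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return model_from_dict(d)


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def _load_packaged(name: str) -> dict:
    ref = resources.files("satcpg.data").joinpath(f"{name}.yaml")
    return yaml.safe_load(ref.read_text())


def _base_model(table: str, override_table: Sequence[dict] | None) -> DemographicModel:
    d = _load_packaged(table)
    if override_table is not None:
        d = dict(d, epochs=list(override_table))
    return model_from_dict(d)


def _truncate_epochs(eps: list[Epoch], cutoff: float) -> list[Epoch]:
    """Drop epochs younger than ``cutoff``; split the epoch spanning it."""
    out: list[Epoch] = []
    for ep in eps:
        if ep.t_end >= cutoff:
            out.append(ep)
        elif ep.t_start > cutoff:
            out.append(replace(ep, t_end=cutoff))
    if not out or out[-1].t_end != cutoff:
        raise ValueError(f"epoch table must span at least {cutoff} generations")
    return out


def build_preset(
    name: str,
    N: float | None = None,
    duration: float | None = None,
    burn_in_multiplier: float | None = None,
    override_table: Sequence[dict] | None = None,
) -> DemographicModel:
    """Build one of the named demographic scenarios.

    ``eur_recent10M`` / ``eur_recent100M`` set the most recent 50 generations
    to a diploid size of 1e7 / 1e8; ``eur_expgrowth`` replaces the recent
    epochs with 4.5 % per-generation exponential growth over the last 196
    generations reaching ~1e8 at present; ``yri_recent10M`` applies the 1e7
    recent epoch to the stylized non-bottleneck trajectory; ``constant``
    requires ``N`` (and optionally a ``duration``, default ``10 * N``).

    ``override_table`` replaces the stylized epoch list (same schema as the
    ``epochs`` key in model files) before the recent-epoch modification.
    """
    if name not in PRESET_NAMES:
        raise ValueError(f"unknown preset {name!r}; valid names: {', '.join(PRESET_NAMES)}")

    if name == "constant":
        if N is None:
            raise ValueError("constant preset requires N")
        dur = float(duration) if duration is not None else 10.0 * float(N)
        model = DemographicModel(
            epochs=(Epoch(dur, 0.0, float(N)),),
            N_ancestral=float(N),
            name="constant",
        )
    elif name in ("eur_recent10M", "eur_recent100M", "eur_expgrowth"):
        base = _base_model("ceu_stylized", override_table)
        eps = list(base.epochs)
        if name == "eur_expgrowth":
            # replace everything younger than 196 generations with exponential
            # growth whose present-day size compounds to ~1e8
            eps = _truncate_epochs(eps, 196.0)
            n_196 = 1e8 / math.exp(GROWTH_4P5 * 196)
            eps.append(Epoch(196.0, 0.0, n_196, growth_rate=GROWTH_4P5))
        else:
            recent_N = 1e7 if name == "eur_recent10M" else 1e8
            eps = _truncate_epochs(eps, 50.0)
            eps.append(Epoch(50.0, 0.0, recent_N))
        model = DemographicModel(
            epochs=tuple(eps),
            N_ancestral=base.N_ancestral,
            burn_in_multiplier=base.burn_in_multiplier,
            name=name,
        )
    else:  # yri_recent10M
        base = _base_model("yri_stylized", override_table)
        eps = _truncate_epochs(list(base.epochs), 50.0)
        eps.append(Epoch(50.0, 0.0, 1e7))
        model = DemographicModel(
            epochs=tuple(eps),
            N_ancestral=base.N_ancestral,
            burn_in_multiplier=base.burn_in_multiplier,
            name=name,
        )

    if burn_in_multiplier is not None:
        model = replace(model, burn_in_multiplier=float(burn_in_multiplier))
    return model


def build_two_population_stub(*args, **kwargs):
    """Structured two-population scenario: configuration stub only."""
    raise NotImplementedError(
        "the structured two-population scenario is out of scope; "
        "only single-population models are implemented"
    )


def resolve_model(spec: str, **kwargs) -> DemographicModel:
    """Resolve a preset name or a model-file path to a model."""
    if spec in PRESET_NAMES:
        return build_preset(spec, **kwargs)
    p = Path(spec)
    if p.exists():
        return load_model(p)
    raise ValueError(
        f"{spec!r} is neither a preset ({', '.join(PRESET_NAMES)}) nor a model file"
    )
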