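"""Parameter container for the Bernoulli autoregressive model.

The full parameter set is α = {a, (π_b, φ_b), {(τ_j, ψ_j)}_j, (π_d, φ_d)}:
an intercept plus one (spike, decay) pair per included component block — the
autoregressive term, each covariate sensor, and the daily seasonal term.
Blocks are optional; an excluded block is ``None`` and contributes nothing
to the linear predictor.  Every included decay must satisfy |decay| < 1 or
the geometric component sums diverge.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np


@dataclass
class ModelParams:
    """α for one target sensor; ``sensors[j] is None`` means sensor j excluded."""

    a: float
    ar: tuple[float, float] | None = None           # (pi_b, phi_b)
    sensors: list[tuple[float, float] | None] = field(default_factory=list)
    seasonal: tuple[float, float] | None = None     # (pi_d, phi_d)

    def __post_init__(self) -> None:
        for name, pair in self._named_pairs():
            if pair is not None:
                spike, decay = pair
                if not abs(decay) < 1:
                    raise ValueError(f"{name} decay {decay} not in (-1, 1)")

    def _named_pairs(self):
        yield "ar", self.ar
        for j, pair in enumerate(self.sensors):
            yield f"sensor[{j}]", pair
        yield "seasonal", self.seasonal

    @property
    def J(self) -> int:
        return len(self.sensors)

    @property
    def k(self) -> int:
        """Number of free parameters: 1 + 2 per included block."""
        return 1 + 2 * sum(pair is not None for _, pair in self._named_pairs())

    # -- flat-vector packing (fixed order: a, AR, sensors in order, seasonal) --

    def pack(self) -> np.ndarray:
        out = [self.a]
        for _, pair in self._named_pairs():
            if pair is not None:
                out.extend(pair)
        return np.asarray(out, dtype=float)

    def unpack(self, vec: np.ndarray) -> "ModelParams":
        """Rebuild params with the same inclusion mask from a flat vector."""
        vec = np.asarray(vec, dtype=float)
        if vec.size != self.k:
            raise ValueError(f"expected {self.k} values, got {vec.size}")
        it = iter(vec)
        a = next(it)
        ar = (next(it), next(it)) if self.ar is not None else None
        sensors: list[tuple[float, float] | None] = []
        for pair in self.sensors:
            sensors.append((next(it), next(it)) if pair is not None else None)
        seasonal = (next(it), next(it)) if self.seasonal is not None else None
        return ModelParams(a, ar, sensors, seasonal)

    def param_names(self, sensor_ids: list[str] | None = None) -> list[str]:
        ids = sensor_ids or [str(j) for j in range(self.J)]
        names = ["a"]
        if self.ar is not None:
            names += ["pi_b", "phi_b"]
        for sid, pair in zip(ids, self.sensors):
            if pair is not None:
                names += [f"tau_{sid}", f"psi_{sid}"]
        if self.seasonal is not None:
            names += ["pi_d", "phi_d"]
        return names

    # -- JSON round-trip ------------------------------------------------------

    def to_dict(self, sensor_ids: list[str] | None = None) -> dict:
        ids = sensor_ids or [str(j) for j in range(self.J)]
        if len(ids) != self.J:
            raise ValueError("sensor_ids length must equal J")
        d: dict = {"a": self.a, "sensor_ids": list(ids)}
        d["include_ar"] = self.ar is not None
        if self.ar is not None:
            d["pi_b"], d["phi_b"] = self.ar
        for sid, pair in zip(ids, self.sensors):
            d[f"include_{sid}"] = pair is not None
            if pair is not None:
                d[f"tau_{sid}"], d[f"psi_{sid}"] = pair
        d["include_seasonal"] = self.seasonal is not None
        if self.seasonal is not None:
            d["pi_d"], d["phi_d"] = self.seasonal
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        ids = d["sensor_ids"]
        ar = (d["pi_b"], d["phi_b"]) if d.get("include_ar") else None
        sensors: list[tuple[float, float] | None] = [
            (d[f"tau_{sid}"], d[f"psi_{sid}"]) if d.get(f"include_{sid}") else None
            for sid in ids
        ]
        seasonal = (d["pi_d"], d["phi_d"]) if d.get("include_seasonal") else None
        return cls(d["a"], ar, sensors, seasonal)

    def to_json(self, path, sensor_ids: list[str] | None = None) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(sensor_ids), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ModelParams":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def intercept_only(J: int, a: float = 0.0) -> ModelParams:
    return ModelParams(a=a, ar=None, sensors=[None] * J, seasonal=None)
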