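"""Parameter containers for the three equivalent model parameterizations.

* ``GLMParams`` — fixed allelic effects ``mu_0, a_j, d_jk`` (and two-locus
  ``(aa), (ad), (da), (dd)``) of the dummy-coded general linear model, with
  reference-allele effects set to zero by construction (reduced shapes m-1).
* ``GMAParams`` — average allelic effects ``mu*, alpha*_j, delta*_jk`` (and
  epistatic terms) of the mean-corrected general multi-allelic model; also
  reduced shapes.
* ``FisherParams`` — the constrained classical parameterization over all m
  alleles; every frequency-weighted sum over any index of any effect array is
  zero.

All three are stored as a mean plus a dict of effect arrays keyed by block
name ("A", "D" for one locus; "A1", "D1", "A2", "D2", "AA", "AD", "DA", "DD"
for two).  Dominance-type axes are stored as full symmetric arrays.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .coding import ONE_LOCUS_BLOCKS, TWO_LOCUS_BLOCKS, pair_indices

CONSTRAINT_TOL = 1e-10

#: axes of each effect array that index locus-1 vs locus-2 alleles, and which
#: pairs of axes are symmetric (dominance-type)
_BLOCK_AXES_2 = {
    "A1": ("1",),
    "D1": ("1", "1"),
    "A2": ("2",),
    "D2": ("2", "2"),
    "AA": ("1", "2"),
    "AD": ("1", "2", "2"),
    "DA": ("1", "1", "2"),
    "DD": ("1", "1", "2", "2"),
}
_BLOCK_AXES_1 = {"A": ("1",), "D": ("1", "1")}


def _sym_axes(axes: tuple[str, ...]) -> list[tuple[int, int]]:
    out = []
    for i in range(len(axes) - 1):
        if axes[i] == axes[i + 1]:
            out.append((i, i + 1))
    return out


def _symmetrize(arr: np.ndarray, axes: tuple[str, ...]) -> np.ndarray:
    for i, j in _sym_axes(axes):
        arr = 0.5 * (arr + np.swapaxes(arr, i, j))
    return arr


@dataclass
class ModelParams:
    """Shared container; use the flavored subclasses in client code."""

    mu: float
    effects: dict[str, np.ndarray]
    m: tuple[int, ...]
    flavor: str = field(init=False, default="")

    _REDUCED = True  # effect axes run over m-1 non-reference alleles

    def __post_init__(self) -> None:
        self.m = tuple(int(x) for x in self.m)
        if not 1 <= len(self.m) <= 2:
            raise ValueError("1 or 2 loci supported")
        axes_map = _BLOCK_AXES_1 if len(self.m) == 1 else _BLOCK_AXES_2
        blocks = ONE_LOCUS_BLOCKS if len(self.m) == 1 else TWO_LOCUS_BLOCKS
        sizes = {
            "1": self.m[0] - (1 if self._REDUCED else 0),
            "2": (self.m[-1] - (1 if self._REDUCED else 0)) if len(self.m) == 2 else None,
        }
        eff: dict[str, np.ndarray] = {}
        for name in blocks:
            axes = axes_map[name]
            shape = tuple(sizes[a] for a in axes)
            arr = self.effects.get(name)
            arr = np.zeros(shape) if arr is None else np.asarray(arr, dtype=float)
            if arr.shape != shape:
                raise ValueError(f"block {name} must have shape {shape}, got {arr.shape}")
            eff[name] = _symmetrize(arr, axes)
        self.effects = eff
        self.mu = float(self.mu)

    @property
    def n_loci(self) -> int:
        return len(self.m)

    @property
    def blocks(self) -> tuple[str, ...]:
        return ONE_LOCUS_BLOCKS if self.n_loci == 1 else TWO_LOCUS_BLOCKS

    def block_vector(self, name: str) -> np.ndarray:
        """Flatten one effect array to the canonical design-column order."""
        arr = self.effects[name]
        axes = (_BLOCK_AXES_1 if self.n_loci == 1 else _BLOCK_AXES_2)[name]
        return _flatten_sym(arr, axes)

    def to_vector(self) -> np.ndarray:
        """Intercept followed by all blocks in canonical order."""
        parts = [np.array([self.mu])]
        parts += [self.block_vector(b) for b in self.blocks]
        return np.concatenate(parts)

    @classmethod
    def from_vector(cls, vec: np.ndarray, m: Sequence[int]) -> "ModelParams":
        m = tuple(int(x) for x in m)
        axes_map = _BLOCK_AXES_1 if len(m) == 1 else _BLOCK_AXES_2
        blocks = ONE_LOCUS_BLOCKS if len(m) == 1 else TWO_LOCUS_BLOCKS
        sizes = {"1": m[0] - 1, "2": m[-1] - 1 if len(m) == 2 else None}
        vec = np.asarray(vec, dtype=float)
        mu, rest = float(vec[0]), vec[1:]
        eff = {}
        pos = 0
        for name in blocks:
            axes = axes_map[name]
            shape = tuple(sizes[a] for a in axes)
            length = _flat_len(shape, axes)
            eff[name] = _unflatten_sym(rest[pos : pos + length], shape, axes)
            pos += length
        if pos != len(rest):
            raise ValueError("coefficient vector has wrong length")
        return cls(mu=mu, effects=eff, m=m)

    def allclose(self, other: "ModelParams", atol: float = 1e-10) -> bool:
        if self.m != other.m:
            return False
        if abs(self.mu - other.mu) > atol:
            return False
        return all(
            np.allclose(self.effects[b], other.effects[b], atol=atol)
            for b in self.blocks
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "flavor": self.flavor,
                "m": list(self.m),
                "mu": self.mu,
                "effects": {k: v.tolist() for k, v in self.effects.items()},
            }
        )


def _flat_len(shape: tuple[int, ...], axes: tuple[str, ...]) -> int:
    n = 1
    i = 0
    while i < len(axes):
        if i + 1 < len(axes) and axes[i] == axes[i + 1]:
            n *= shape[i] * (shape[i] + 1) // 2
            i += 2
        else:
            n *= shape[i]
            i += 1
    return n


def _flatten_sym(arr: np.ndarray, axes: tuple[str, ...]) -> np.ndarray:
    """Flatten, taking only the upper triangle of symmetric axis pairs."""
    groups: list[list[tuple[int, ...]]] = []
    i = 0
    while i < len(axes):
        if i + 1 < len(axes) and axes[i] == axes[i + 1]:
            groups.append([(j, k) for j, k in pair_indices(arr.shape[i])])
            i += 2
        else:
            groups.append([(j,) for j in range(arr.shape[i])])
            i += 1
    out = []
    from itertools import product

    for combo in product(*groups):
        idx = tuple(x for grp in combo for x in grp)
        out.append(arr[idx])
    return np.asarray(out, dtype=float)


def _unflatten_sym(
    vec: np.ndarray, shape: tuple[int, ...], axes: tuple[str, ...]
) -> np.ndarray:
    arr = np.zeros(shape)
    groups: list[list[tuple[int, ...]]] = []
    i = 0
    while i < len(axes):
        if i + 1 < len(axes) and axes[i] == axes[i + 1]:
            groups.append(pair_indices(shape[i]))
            i += 2
        else:
            groups.append([(j,) for j in range(shape[i])])
            i += 1
    from itertools import product

    for val, combo in zip(vec, product(*groups)):
        idxs = [tuple(x for grp in c for x in grp) for c in product(*[_expand(g) for g in combo])]
        for idx in idxs:
            arr[idx] = val
    return arr


def _expand(grp: tuple[int, ...]) -> list[tuple[int, ...]]:
    if len(grp) == 2 and grp[0] != grp[1]:
        return [grp, (grp[1], grp[0])]
    return [grp]


class GLMParams(ModelParams):
    """Fixed allelic effects of the dummy-coded GLM (reference effects = 0)."""

    def __post_init__(self) -> None:
        super().__post_init__()
        self.flavor = "glm"


class GMAParams(ModelParams):
    """Average allelic effects of the mean-corrected GMA model."""

    def __post_init__(self) -> None:
        super().__post_init__()
        self.flavor = "gma"


class FisherParams(ModelParams):
    """Constrained classical parameterization over all m alleles.

    Every frequency-weighted sum of any effect array over any index is zero;
    :meth:`check_constraints` verifies this against a frequency set.
    """

    _REDUCED = False

    def __post_init__(self) -> None:
        super().__post_init__()
        self.flavor = "fisher"

    def check_constraints(
        self, freqs: Sequence[np.ndarray], tol: float = CONSTRAINT_TOL
    ) -> None:
        axes_map = _BLOCK_AXES_1 if self.n_loci == 1 else _BLOCK_AXES_2
        ps = {"1": np.asarray(freqs[0], float)}
        if self.n_loci == 2:
            ps["2"] = np.asarray(freqs[1], float)
        for name, arr in self.effects.items():
            for axis, tag in enumerate(axes_map[name]):
                s = np.tensordot(ps[tag], arr, axes=([0], [axis]))
                if np.max(np.abs(s)) > tol:
                    raise ValueError(
                        f"constraint violated for block {name} along axis {axis}: "
                        f"max |weighted sum| = {np.max(np.abs(s)):.3e}"
                    )


def params_from_json(text: str) -> ModelParams:
    obj = json.loads(text)
    cls = {"glm": GLMParams, "gma": GMAParams, "fisher": FisherParams}[obj["flavor"]]
    return cls(mu=obj["mu"], effects={k: np.asarray(v) for k, v in obj["effects"].items()}, m=tuple(obj["m"]))
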