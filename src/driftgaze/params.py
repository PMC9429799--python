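"""Diffusion-model parameter containers and model-variant bookkeeping.

Conventions: the diffusion constant is fixed at 1, time is in seconds,
evidence is accumulated between an absorbing boundary at 0 (noise-patch
choice) and one at ``a`` (face choice). The process starts at ``zr * a``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

#: Condition labels: inspection identity (Face/Noise) x preview (Preview/Outline).
CONDITIONS = ("FP", "FO", "NP", "NO")

#: Parameters that a model variant may free across conditions.
VARIABLE_PARAMS = ("v", "a", "t0")


@dataclass(frozen=True)
class DDMParams:
    """Parameters of a Wiener diffusion process with across-trial variability.

    Attributes
    ----------
    a : float
        Boundary separation (> 0), in evidence units.
    zr : float
        Relative starting point in (0, 1); absolute start is ``zr * a``.
    v : float
        Mean drift rate (evidence per second); positive drifts approach the
        upper (face) boundary.
    t0 : float
        Mean non-decision time in seconds (>= 0).
    sv : float
        SD of the normal across-trial drift-rate distribution (>= 0).
    sz : float
        Width of the uniform across-trial starting-point distribution, in
        relative units (>= 0); per-trial start is ``zr +- sz/2``.
    st0 : float
        Width of the uniform across-trial non-decision-time distribution in
        seconds (>= 0); per-trial non-decision time is ``t0 +- st0/2``.
    """

    a: float
    zr: float
    v: float
    t0: float = 0.0
    sv: float = 0.0
    sz: float = 0.0
    st0: float = 0.0

    def validate(self) -> "DDMParams":
        if not self.a > 0:
            raise ValueError(f"boundary separation a must be > 0, got {self.a}")
        if not (0 < self.zr - self.sz / 2 and self.zr + self.sz / 2 < 1):
            raise ValueError(
                f"starting point zr={self.zr} with sz={self.sz} leaves (0, 1)"
            )
        if min(self.sv, self.sz, self.st0) < 0:
            raise ValueError("variability parameters sv, sz, st0 must be >= 0")
        if self.t0 - self.st0 / 2 < 0:
            raise ValueError(
                f"non-decision time t0={self.t0} with st0={self.st0} can go negative"
            )
        return self

    @property
    def z(self) -> float:
        """Absolute starting point ``zr * a``."""
        return self.zr * self.a

    def without_variability(self) -> "DDMParams":
        return replace(self, sv=0.0, sz=0.0, st0=0.0)


@dataclass(frozen=True)
class VariantSpec:
    """One member of the eight-model family.

    ``free`` names the parameters (subset of ``{v, a, t0}``) that take a
    separate value in each of the four conditions; everything else — and
    always ``zr``, ``sv``, ``sz``, ``st0`` — is shared across conditions.
    """

    free: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        bad = set(self.free) - set(VARIABLE_PARAMS)
        if bad:
            raise ValueError(f"cannot free parameters {sorted(bad)} across conditions")
        object.__setattr__(self, "free", frozenset(self.free))

    @property
    def k(self) -> int:
        """Number of free parameters: 7 shared + 3 extra per freed parameter."""
        return 7 + 3 * len(self.free)

    @property
    def name(self) -> str:
        if not self.free:
            return "none"
        return "+".join(p for p in VARIABLE_PARAMS if p in self.free)

    def nests(self, other: "VariantSpec") -> bool:
        """True if ``other``'s free set is a subset of this variant's."""
        return other.free <= self.free

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"VariantSpec({self.name})"


def all_variants() -> list[VariantSpec]:
    """The eight variants, ordered by parameter count then by name."""
    variants = []
    for mask in range(8):
        free = frozenset(
            p for i, p in enumerate(VARIABLE_PARAMS) if mask >> i & 1
        )
        variants.append(VariantSpec(free))
    variants.sort(key=lambda s: (s.k, s.name))
    return variants


def params_by_condition(
    shared: DDMParams, per_condition: dict[str, dict[str, float]] | None = None
) -> dict[str, DDMParams]:
    """Expand a shared parameter set into one :class:`DDMParams` per condition.

    ``per_condition`` maps condition label -> overrides, e.g.
    ``{"FP": {"v": 0.607, "t0": 0.208}}``.
    """
    per_condition = per_condition or {}
    out = {}
    for cond in CONDITIONS:
        out[cond] = replace(shared, **per_condition.get(cond, {})).validate()
    return out
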