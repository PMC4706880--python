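"""Synthetic sensory world: feature-vector streams with controllable novelty.

Features are abstract integer identifiers partitioned into areas.  A
*context* is a fixed sparse feature pattern; a presentation of a context with
novelty fraction nu replaces a nu-share of the context's active features with
features never used by any context (drawn per area from a reserved pool), so
the novelty label is genuine by construction.  Events are ordered sequences
of overlapping context windows, each moment carrying nonzero novelty so that
encoding drives expansion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np


class NoveltyExhaustedError(RuntimeError):
    """A stimulus requested more novel features than the reserve holds."""


@dataclass(frozen=True)
class Stimulus:
    active: frozenset
    novelty_label: float
    context: int = 0
    event_id: Optional[int] = None
    moment_index: Optional[int] = None


@dataclass
class WorldConfig:
    n_features: int = 256
    n_areas: int = 4
    n_contexts: int = 2
    pattern_density: float = 0.25
    novelty_fraction: float = 0.25
    event_length: int = 3
    event_overlap: float = 0.5     # minimum feature overlap between consecutive moments
    event_novelty: float = 0.2     # novel-feature share per moment
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.pattern_density < 1.0):
            raise ValueError("pattern_density must lie in (0, 1)")
        if not (0.0 <= self.novelty_fraction <= 1.0):
            raise ValueError("novelty_fraction must lie in [0, 1]")
        if self.n_features % self.n_areas != 0:
            raise ValueError("n_features must divide evenly into areas")

    @property
    def features_per_area(self) -> int:
        return self.n_features // self.n_areas

    def area_of(self, feature: int) -> int:
        return feature // self.features_per_area


class World:
    """Context patterns, the novelty reserve, and stimulus generation.

    All sampling is integer-only from a seeded ``numpy`` generator, so a given
    seed reproduces the identical stream on any platform.
    """

    def __init__(self, cfg: WorldConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.rng_seed)
        fpa = cfg.features_per_area
        per_area_active = max(1, round(cfg.pattern_density * fpa))
        # Contexts draw from the first ~60% of each area block; the remainder
        # is the guaranteed-novel reserve.
        pool = max(per_area_active + 1, int(fpa * 0.6))
        self.contexts: list[frozenset] = []
        for _ in range(cfg.n_contexts):
            feats = []
            for a in range(cfg.n_areas):
                base = a * fpa
                feats.extend(base + rng.choice(pool, size=per_area_active, replace=False))
            self.contexts.append(frozenset(int(f) for f in feats))
        used = frozenset().union(*self.contexts) if self.contexts else frozenset()
        self.reserve_by_area: list[list[int]] = []
        for a in range(cfg.n_areas):
            block = range(a * fpa, (a + 1) * fpa)
            self.reserve_by_area.append([f for f in block if f not in used])
        self.all_context_features = used

    def context_features_by_area(self, context: int) -> list[list[int]]:
        fpa = self.cfg.features_per_area
        out: list[list[int]] = [[] for _ in range(self.cfg.n_areas)]
        for f in sorted(self.contexts[context]):
            out[f // fpa].append(f)
        return out

    def _novelize(self, base: Sequence[int], nu: float, rng: np.random.Generator) -> frozenset:
        """Replace a nu-fraction of ``base`` with same-area reserve features."""
        base = sorted(base)
        n_replace = round(nu * len(base))
        if n_replace == 0:
            return frozenset(base)
        drop_idx = rng.choice(len(base), size=n_replace, replace=False)
        dropped = [base[i] for i in drop_idx]
        kept = [f for i, f in enumerate(base) if i not in set(int(j) for j in drop_idx)]
        novel: list[int] = []
        need: dict[int, int] = {}
        for f in dropped:
            a = self.cfg.area_of(f)
            need[a] = need.get(a, 0) + 1
        for a, k in need.items():
            reserve = self.reserve_by_area[a]
            if k > len(reserve):
                raise NoveltyExhaustedError(
                    f"area {a}: requested {k} novel features, reserve has {len(reserve)}")
            novel.extend(int(x) for x in rng.choice(reserve, size=k, replace=False))
        return frozenset(kept) | frozenset(novel)


def generate_stream(world: World, schedule: Sequence[dict],
                    rng: Optional[np.random.Generator] = None) -> list[Stimulus]:
    """Expand a block schedule into an ordered stimulus list.

    Each block is ``{"context": int, "novelty_fraction": float,
    "n_presentations": int}``.  Deterministic given the generator seed.
    """
    if rng is None:
        rng = np.random.default_rng(world.cfg.rng_seed + 1)
    stream: list[Stimulus] = []
    for block in schedule:
        ctx = int(block.get("context", 0))
        nu = float(block.get("novelty_fraction", world.cfg.novelty_fraction))
        n = int(block["n_presentations"])
        base = sorted(world.contexts[ctx])
        for _ in range(n):
            active = world._novelize(base, nu, rng)
            stream.append(Stimulus(active=active, novelty_label=nu, context=ctx))
    return stream


def generate_event(world: World, event_length: Optional[int] = None,
                   context: int = 0, event_id: int = 0,
                   rng: Optional[np.random.Generator] = None) -> list[Stimulus]:
    """Build a multi-moment event: overlapping windows over one context's
    features, each moment carrying nonzero novelty.

    Consecutive moments share at least ``event_overlap`` of their features
    before novelty injection.  Zero requested novelty is refused: an event
    with no novelty would drive no expansion and could not be encoded.
    """
    cfg = world.cfg
    if event_length is None:
        event_length = cfg.event_length
    if cfg.event_novelty <= 0.0:
        raise ValueError("events must carry nonzero novelty to be encodable")
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed + 2)
    per_area = world.context_features_by_area(context)
    n_in_area = len(per_area[0])
    # windows slide across the ordered context features without wrapping, so
    # each moment introduces genuinely fresh content; consecutive windows
    # share at least the configured overlap.
    win = max(2, round(n_in_area * (0.5 + cfg.event_overlap / 4)))
    stride = max(1, (n_in_area - win) // max(1, event_length - 1))
    if (win - stride) / win < cfg.event_overlap:
        win = min(n_in_area, stride + max(1, round(cfg.event_overlap * win)))
    moments: list[Stimulus] = []
    for m in range(event_length):
        feats: list[int] = []
        for area_feats in per_area:
            n = len(area_feats)
            start = min(m * stride, max(0, n - win))
            feats.extend(area_feats[start: start + min(win, n)])
        active = world._novelize(feats, cfg.event_novelty, rng)
        moments.append(Stimulus(active=active, novelty_label=cfg.event_novelty,
                                context=context, event_id=event_id, moment_index=m))
    return moments


def measured_novelty(world: World, stim: Stimulus) -> float:
    """Fraction of a stimulus' features outside every context pattern."""
    if not stim.active:
        return 0.0
    novel = sum(1 for f in stim.active if f not in world.all_context_features)
    return novel / len(stim.active)
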