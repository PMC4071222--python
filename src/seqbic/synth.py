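"""Synthetic expression matrices with planted order-preserving biclusters.

The generator reproduces a standard benchmark protocol: an i.i.d. random
background (uniform on (-1, 1) or standard normal), a handful of planted
biclusters whose row/column counts are drawn uniformly from per-setting
ranges (with row/column picks independent across biclusters, so overlaps
occur), an order-preserving or multiplicative value model inside each
bicluster, optional per-row sign flips (symmetries), additive noise bounded
by a fraction of the domain range, and uniformly injected missing values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .matrix import Bicluster, BiclusterSet, ExpressionMatrix


@dataclass
class SyntheticSetting:
    """Generator configuration.

    ``noise_factor`` bounds the additive noise at +-noise_factor * range of
    the background domain (range 2 for the uniform background; the 6-sigma
    convention, range 6, for the gaussian one).  ``replace_rate`` replaces
    that fraction of all matrix cells with fresh background draws after
    planting (the corruption used to probe the closing operators).
    ``symmetry_rate`` is the fraction of each bicluster's rows whose values
    are negated before noise.
    """

    n: int = 100
    m: int = 30
    k: int = 2
    row_range: tuple[int, int] = (10, 20)
    col_range: tuple[int, int] = (5, 7)
    background: str = "uniform"        # "uniform" U(-1,1) | "gaussian" N(0,1)
    model: str = "order_preserving"    # | "multiplicative"
    noise_factor: float = 0.10
    replace_rate: float = 0.0
    missing_rate: float = 0.0
    symmetry_rate: float = 0.0
    seed: int = 0

    def domain_range(self) -> float:
        return 2.0 if self.background == "uniform" else 6.0


#: benchmark presets: matrix size, planted bicluster count and size ranges
PRESETS: dict[str, SyntheticSetting] = {
    "s100x30": SyntheticSetting(100, 30, 2, (10, 20), (5, 7)),
    "s500x50": SyntheticSetting(500, 50, 3, (40, 70), (6, 8)),
    "s1000x75": SyntheticSetting(1000, 75, 5, (100, 150), (7, 9)),
    "s2000x100": SyntheticSetting(2000, 100, 8, (200, 300), (8, 10)),
}


def preset(name: str, **overrides) -> SyntheticSetting:
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return replace(PRESETS[name], **overrides)


def generate(setting: SyntheticSetting) -> tuple[ExpressionMatrix, BiclusterSet]:
    """Draw one matrix and its hidden bicluster set.

    Later plantings overwrite earlier values in shared cells, which can
    harden recovery of overlapped biclusters.  Fixed seeds give bit-identical
    output.
    """
    s = setting
    if s.row_range[1] > s.n or s.col_range[1] > s.m:
        raise ValueError("planted bicluster ranges exceed the matrix dimensions")
    rng = np.random.default_rng(s.seed)
    if s.background == "uniform":
        values = rng.uniform(-1, 1, size=(s.n, s.m))
        draw = lambda size: rng.uniform(-1, 1, size=size)
    elif s.background == "gaussian":
        values = rng.standard_normal((s.n, s.m))
        draw = lambda size: rng.standard_normal(size)
    else:
        raise ValueError(f"unknown background {s.background!r}")

    hidden = []
    amp = s.noise_factor * s.domain_range()
    for _ in range(s.k):
        nr = int(rng.integers(s.row_range[0], s.row_range[1] + 1))
        nc = int(rng.integers(s.col_range[0], s.col_range[1] + 1))
        rows = np.sort(rng.choice(s.n, size=nr, replace=False))
        cols = np.sort(rng.choice(s.m, size=nc, replace=False))
        pi = rng.permutation(nc)  # pi[t] = position in `cols` of the t-th smallest
        if s.model == "order_preserving":
            vals = np.sort(draw((nr, nc)), axis=1)
            block = np.empty((nr, nc))
            block[:, pi] = vals
        elif s.model == "multiplicative":
            base = np.sort(draw(nc))
            scale = rng.uniform(0.5, 2.0, size=nr)
            block = np.empty((nr, nc))
            block[:, pi] = scale[:, None] * base[None, :]
        else:
            raise ValueError(f"unknown model {s.model!r}")
        signs = np.ones(nr, dtype=int)
        if s.symmetry_rate > 0:
            nflip = int(round(s.symmetry_rate * nr))
            flip = rng.choice(nr, size=nflip, replace=False)
            signs[flip] = -1
            block = block * signs[:, None]
        if amp > 0:
            block = block + rng.uniform(-amp, amp, size=block.shape)
        values[np.ix_(rows, cols)] = block
        perm = tuple((int(cols[pi[t]]),) for t in range(nc))
        hidden.append(
            Bicluster(
                frozenset(int(r) for r in rows),
                frozenset(int(c) for c in cols),
                perm,
                tuple(int(x) for x in signs),
            )
        )

    if s.replace_rate > 0:
        n_rep = int(round(s.replace_rate * s.n * s.m))
        flat = rng.choice(s.n * s.m, size=n_rep, replace=False)
        repl = draw(n_rep)
        values.flat[flat] = repl

    missing = np.zeros((s.n, s.m), dtype=bool)
    n_miss = int(round(s.missing_rate * s.n * s.m))
    if n_miss:
        flat = rng.choice(s.n * s.m, size=n_miss, replace=False)
        missing.flat[flat] = True
        values = np.where(missing, np.nan, values)

    matrix = ExpressionMatrix(
        values,
        [f"x{i + 1}" for i in range(s.n)],
        [f"y{j + 1}" for j in range(s.m)],
        missing,
    )
    prov = {"setting": s.__dict__.copy()}
    return matrix, BiclusterSet(hidden, prov)


def batch(
    setting: SyntheticSetting, n_uniform: int, n_gaussian: int
) -> list[tuple[ExpressionMatrix, BiclusterSet]]:
    """Generate instances with derived, pairwise distinct sub-seeds."""
    ss = np.random.SeedSequence(setting.seed)
    subs = ss.spawn(n_uniform + n_gaussian)
    out = []
    for idx, sub in enumerate(subs):
        bg = "uniform" if idx < n_uniform else "gaussian"
        sub_seed = int(sub.generate_state(1)[0] % (2**31 - 1))
        out.append(generate(replace(setting, background=bg, seed=sub_seed)))
    return out
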