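"""Synthetic connectome cohorts with a matrix-level lesion model.

Generates cohorts of healthy and lesioned structural connectomes (default
83 regions, mirroring the Lausanne-2008 cortical/subcortical scale, with
20 stroke and 10 control subjects) plus surrogate BOLD series, so the
whole pipeline is exercisable without any imaging data.

The healthy generator emulates deterministic-tractography outputs:
regions are placed uniformly in a 70 mm-radius sphere, tract lengths are
the Euclidean inter-region distances, streamline counts decay with
distance as ``S_ij = round(S_max * exp(-L_ij / lambda))``, per-pathway FA
is uniform in [0.2, 0.8] (above the 0.20 FA tracking-stop threshold), and
weights are the product ``FA_ij * S_ij``.

The lesion model acts on matrices, not images: a fully damaged region
loses every incident pathway (tracking cannot enter it), and a partially
damaged region keeps its pathways with streamline counts scaled by
``1 - damage``, so every incident weight scales by the same factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectome import StructuralConnectome, binarize

__all__ = [
    "LesionSpec",
    "CohortSpec",
    "generate_healthy_connectome",
    "apply_lesion",
    "generate_cohort",
    "generate_surrogate_bold",
]

#: distance-decay constant for streamline counts, mm
DEFAULT_LAMBDA_MM = 40.0
#: streamline count of a zero-length pathway before decay
DEFAULT_S_MAX = 200
#: sphere radius for synthetic region placement, mm
DEFAULT_RADIUS_MM = 70.0
#: fraction of region pairs kept as pathways (weakest pruned to zero)
DEFAULT_EDGE_DENSITY = 0.3


@dataclass
class LesionSpec:
    """A virtual lesion: which regions are damaged and how badly.

    ``damage_fraction[i] = 1`` removes every pathway incident to
    ``lesioned_regions[i]``; fractions below 1 attenuate them.
    """

    lesioned_regions: list[int]
    damage_fraction: list[float]
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.lesioned_regions) != len(self.damage_fraction):
            raise ValueError("one damage fraction per lesioned region required")
        if len(set(self.lesioned_regions)) != len(self.lesioned_regions):
            raise ValueError("lesioned region indices must be unique")
        if any(not (0.0 <= f <= 1.0) for f in self.damage_fraction):
            raise ValueError("damage fractions must lie in [0, 1]")


@dataclass
class CohortSpec:
    """Study-design parameters for a synthetic cohort.

    Defaults mirror the modeled study: 20 stroke cases, 10 controls,
    83 regions; one lesion per stroke subject spanning 1–8 regions with
    damage fractions in [0.3, 1.0].
    """

    n_control: int = 10
    n_stroke: int = 20
    n_regions: int = 83
    seed: int = 0
    lesion_size_range: tuple[int, int] = (1, 8)
    damage_range: tuple[float, float] = (0.3, 1.0)
    edge_density: float = DEFAULT_EDGE_DENSITY

    def __post_init__(self) -> None:
        if self.n_control < 0 or self.n_stroke < 0 or self.n_control + self.n_stroke == 0:
            raise ValueError("cohort must contain at least one subject")
        if self.n_regions < 2:
            raise ValueError("n_regions must be >= 2")
        if self.lesion_size_range[0] > self.lesion_size_range[1]:
            raise ValueError("lesion_size_range must be ordered")
        if self.damage_range[0] > self.damage_range[1]:
            raise ValueError("damage_range must be ordered")


def _graph_connected(weights: np.ndarray) -> bool:
    n = weights.shape[0]
    seen = np.zeros(n, dtype=bool)
    stack = [0]
    seen[0] = True
    while stack:
        i = stack.pop()
        for j in np.nonzero(weights[i] > 0)[0]:
            if not seen[j]:
                seen[j] = True
                stack.append(j)
    return bool(seen.all())


def generate_healthy_connectome(
    n_regions: int = 83,
    seed: int = 0,
    *,
    edge_density: float = DEFAULT_EDGE_DENSITY,
    decay_mm: float = DEFAULT_LAMBDA_MM,
    s_max: int = DEFAULT_S_MAX,
    radius_mm: float = DEFAULT_RADIUS_MM,
    subject_id: str | None = None,
    return_factors: bool = False,
):
    """Generate one healthy synthetic connectome.

    Regenerates with the next seed (logged in the returned subject id as
    ``+k``) in the unlikely case the binarized graph is disconnected, so
    the healthy baseline always supports efficiency comparisons.

    With ``return_factors=True`` also returns ``(FA, S)`` so callers can
    verify ``weights == FA * S`` elementwise.
    """
    if n_regions < 2:
        raise ValueError("n_regions must be >= 2")
    for attempt in range(20):
        rng = np.random.default_rng(seed + attempt)
        # uniform positions in a sphere via rejection sampling
        pos = np.empty((n_regions, 3))
        filled = 0
        while filled < n_regions:
            cand = rng.uniform(-radius_mm, radius_mm, size=(2 * n_regions, 3))
            cand = cand[np.linalg.norm(cand, axis=1) <= radius_mm]
            take = min(len(cand), n_regions - filled)
            pos[filled : filled + take] = cand[:take]
            filled += take
        diff = pos[:, None, :] - pos[None, :, :]
        lengths = np.sqrt((diff**2).sum(axis=2))
        np.fill_diagonal(lengths, 0.0)
        lengths = (lengths + lengths.T) / 2.0

        streamlines = np.round(s_max * np.exp(-lengths / decay_mm))
        fa = rng.uniform(0.2, 0.8, size=(n_regions, n_regions))
        fa = (fa + fa.T) / 2.0
        np.fill_diagonal(streamlines, 0.0)

        # sparsify: keep the strongest edge_density fraction of pairs
        iu = np.triu_indices(n_regions, k=1)
        order = np.argsort(streamlines[iu], kind="stable")
        n_pairs = len(order)
        # keep at least a spanning tree's worth of edges so connectivity
        # is attainable at small n
        n_keep = max(int(round(edge_density * n_pairs)), n_regions - 1)
        n_drop = n_pairs - n_keep
        drop = order[:n_drop]
        mask = np.ones((n_regions, n_regions), dtype=bool)
        mask[iu[0][drop], iu[1][drop]] = False
        mask[iu[1][drop], iu[0][drop]] = False
        np.fill_diagonal(mask, False)
        streamlines = np.where(mask, streamlines, 0.0)
        fa = np.where(mask, fa, 0.0)
        weights = fa * streamlines
        # decay can round distant counts to zero; keep lengths only for pathways
        lengths_out = np.where(weights > 0, lengths, 0.0)
        if not _graph_connected(weights):
            continue
        sid = subject_id or f"synthetic-{seed}"
        if attempt:
            sid += f"+{attempt}"
        c = StructuralConnectome(
            subject_id=sid,
            region_labels=[f"region_{i:03d}" for i in range(n_regions)],
            weights=weights,
            lengths=lengths_out,
            group_label="control",
        )
        if return_factors:
            return c, fa, streamlines
        return c
    raise RuntimeError("could not generate a connected connectome in 20 attempts")


def apply_lesion(c: StructuralConnectome, spec: LesionSpec) -> StructuralConnectome:
    """Attenuate or remove pathways incident to lesioned regions.

    Damage fraction ``f`` scales every incident streamline count by
    ``1 - f`` before the FA × streamlines product is re-formed, i.e. the
    incident weights scale by exactly ``1 - f``; ``f = 1`` zeroes the
    region's row and column.  Lengths of surviving pathways are
    unchanged.  A pathway between two lesioned regions is attenuated by
    both factors.
    """
    n = c.n_regions
    for idx in spec.lesioned_regions:
        if not 0 <= idx < n:
            raise IndexError(f"lesioned region {idx} out of range for n={n}")
    factor = np.ones(n)
    for idx, f in zip(spec.lesioned_regions, spec.damage_fraction):
        factor[idx] *= 1.0 - f
    weights = c.weights * factor[:, None] * factor[None, :]
    lengths = np.where(weights > 0, c.lengths, 0.0)
    out = c.copy(group_label="stroke")
    out.weights = weights
    out.lengths = lengths
    out.lesion_meta = {
        "regions": list(map(int, spec.lesioned_regions)),
        "damage": list(map(float, spec.damage_fraction)),
    }
    out.validate()
    return out


def generate_cohort(spec: CohortSpec) -> list[StructuralConnectome]:
    """Generate ``n_control + n_stroke`` subjects deterministically.

    Per-subject seeds are spawned from the cohort seed; stroke subjects
    receive one lesion with size and damage drawn from the spec ranges.
    """
    master = np.random.default_rng(spec.seed)
    subject_seeds = master.integers(0, 2**31 - 1, size=spec.n_control + spec.n_stroke)
    cohort: list[StructuralConnectome] = []
    for i in range(spec.n_control):
        c = generate_healthy_connectome(
            spec.n_regions,
            seed=int(subject_seeds[i]),
            edge_density=spec.edge_density,
            subject_id=f"control-{i:02d}",
        )
        cohort.append(c)
    for k in range(spec.n_stroke):
        seed = int(subject_seeds[spec.n_control + k])
        healthy = generate_healthy_connectome(
            spec.n_regions,
            seed=seed,
            edge_density=spec.edge_density,
            subject_id=f"stroke-{k:02d}",
        )
        rng = np.random.default_rng(seed + 1)
        lo, hi = spec.lesion_size_range
        size = int(rng.integers(lo, hi + 1))
        size = min(size, spec.n_regions - 1)
        regions = rng.choice(spec.n_regions, size=size, replace=False)
        damage = rng.uniform(*spec.damage_range, size=size)
        lesion = LesionSpec(
            lesioned_regions=[int(r) for r in regions],
            damage_fraction=[float(d) for d in damage],
            seed=seed,
        )
        cohort.append(apply_lesion(healthy, lesion))
    return cohort


def generate_surrogate_bold(
    n_regions: int,
    duration_s: float,
    tr_s: float = 2.0,
    seed: int = 0,
    *,
    n_communities: int = 4,
    community_strength: float = 0.5,
    cutoff_hz: float = 0.25,
):
    """Band-limited correlated Gaussian surrogate for empirical BOLD.

    Signals are built in the frequency domain with power only at
    frequencies <= ``cutoff_hz`` (hard cutoff, so leakage is zero) and a
    block community correlation structure: regions in the same community
    share a common component with weight ``community_strength``.

    Returns a :class:`~neuromass.simulator.BOLDSeries` with provenance
    ``surrogate``.
    """
    from .simulator import BOLDSeries  # local import avoids a cycle

    if duration_s < tr_s or tr_s <= 0:
        raise ValueError("duration must cover at least one TR and tr_s must be > 0")
    n_t = int(np.floor(duration_s / tr_s))
    rng = np.random.default_rng(seed)
    fs = 1.0 / tr_s
    freqs = np.fft.rfftfreq(n_t, d=tr_s)
    band = (freqs > 0) & (freqs <= cutoff_hz + 1e-12)

    def band_limited(n_series: int) -> np.ndarray:
        spec = np.zeros((n_series, len(freqs)), dtype=complex)
        k = band.sum()
        spec[:, band] = rng.standard_normal((n_series, k)) + 1j * rng.standard_normal(
            (n_series, k)
        )
        x = np.fft.irfft(spec, n=n_t, axis=1)
        sd = x.std(axis=1, ddof=1, keepdims=True)
        sd[sd == 0] = 1.0
        return x / sd

    common = band_limited(n_communities)
    own = band_limited(n_regions)
    membership = np.arange(n_regions) % n_communities
    w = community_strength
    data = w * common[membership] + np.sqrt(1.0 - w**2) * own
    return BOLDSeries(
        subject_id=f"surrogate-{seed}",
        data=data,
        tr_s=tr_s,
        provenance="surrogate",
    )
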