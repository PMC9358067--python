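"""Synthetic topologies and class-conditional feature matrices.

The generator produces grammar-valid topology strings for the eight protein
groups -- {globular, single-helix alpha, multi-helix alpha, beta barrel} x
{with, without signal peptide} -- and pairs them with L x D feature matrices
whose rows are noisy class centroids smoothed along the sequence.  It is a
deliberately simple Gaussian-mixture feature model, not an embedding
simulator: its one job is to provide a tunable amount of per-residue class
signal so that training, decoding and evaluation can be exercised end to end
without external data.

Segment-length distributions (rounded normals, clipped):

=========  ==============  =========
segment    distribution    clip
=========  ==============  =========
helix      N(21, 3)        [12, 35]
strand     N(9, 2)         [6, 14]
signal     N(20, 3)        [10, 40]
=========  ==============  =========

Loops are at least 3 residues.  Beta barrels have an even strand count in
8..22; multi-helix proteins have 2..12 helices.  Orientation (the case of
B/H) never influences the feature distribution, so direction is recoverable
only through the decoder grammar, mirroring the 5-class scoring head.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from memtop.io_formats import (
    CLASS_INDEX,
    LabelSequence,
    ProteinRecord,
    parse_labels,
    write_fasta,
    write_feature_container,
    write_labels,
)

__all__ = ["GeneratorConfig", "SyntheticProtein", "sample_topology", "sample_features",
           "class_centroids", "generate_dataset", "GROUPS"]

#: (topology kind, has signal peptide) pairs, fixed order
GROUPS: tuple[tuple[str, bool], ...] = tuple(
    (kind, sp) for kind in ("globular", "alpha_single", "alpha_multi", "beta")
    for sp in (False, True)
)

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic generator; defaults define the standard benchmark set."""

    feature_dim: int = 32
    class_separation: float = 2.0   # distance scale between class centroids
    noise_sd: float = 1.0           # per-dimension residue noise
    context_smoothing: int = 2      # moving-average half-width along the sequence
    mix: tuple[float, ...] = (0.125,) * 8   # proportions over GROUPS
    length_range: tuple[int, int] = (80, 400)
    helix_len: tuple[float, float, int, int] = (21.0, 3.0, 12, 35)   # mean, sd, lo, hi
    strand_len: tuple[float, float, int, int] = (9.0, 2.0, 6, 14)
    sp_len: tuple[float, float, int, int] = (20.0, 3.0, 10, 40)
    loop_min: int = 3
    strand_count: tuple[int, int] = (8, 22)    # even counts within this range
    helix_count: tuple[int, int] = (2, 12)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.mix) != len(GROUPS):
            raise ValueError(f"mix must have {len(GROUPS)} entries (groups {GROUPS})")
        if abs(sum(self.mix) - 1.0) > 1e-9:
            raise ValueError("mix proportions must sum to 1")
        for lo_name, (_, _, lo, _hi) in [("helix", self.helix_len), ("strand", self.strand_len),
                                         ("sp", self.sp_len)]:
            if lo < 5:
                raise ValueError(f"{lo_name} minimum length {lo} below the decoder minimum of 5")


@dataclass(frozen=True)
class SyntheticProtein:
    record: ProteinRecord
    labels: LabelSequence
    features: np.ndarray
    group: tuple[str, bool]


def _clipped_normal(rng: np.random.Generator, spec: tuple[float, float, int, int]) -> int:
    mean, sd, lo, hi = spec
    return int(np.clip(round(rng.normal(mean, sd)), lo, hi))


def sample_topology(rng: np.random.Generator, kind: str, has_sp: bool,
                    config: GeneratorConfig = GeneratorConfig()) -> LabelSequence:
    """Draw one grammar-valid topology string for the given group.

    Segment counts and lengths are drawn from the config distributions; the
    remaining residue budget is spread over the loops (each >= loop_min).
    Infeasible draws (budget exceeding the target length) are resampled, with
    an error after 100 attempts.
    """
    if kind not in ("globular", "alpha_single", "alpha_multi", "beta"):
        raise ValueError(f"unknown topology kind {kind!r}")
    lo, hi = config.length_range
    for _ in range(100):
        L = int(rng.integers(lo, hi + 1))
        if kind == "globular":
            n_tm, tm_char_spec = 0, None
        elif kind == "alpha_single":
            n_tm, tm_char_spec = 1, config.helix_len
        elif kind == "alpha_multi":
            clo, chi = config.helix_count
            n_tm, tm_char_spec = int(rng.integers(clo, chi + 1)), config.helix_len
        else:
            clo, chi = config.strand_count
            n_tm = 2 * int(rng.integers(clo // 2, chi // 2 + 1))
            tm_char_spec = config.strand_len
        tm_lens = [_clipped_normal(rng, tm_char_spec) for _ in range(n_tm)]
        sp = _clipped_normal(rng, config.sp_len) if has_sp else 0
        n_loops = n_tm + 1
        budget = sp + sum(tm_lens) + config.loop_min * n_loops
        if budget > L:
            continue
        extra = rng.multinomial(L - budget, np.full(n_loops, 1.0 / n_loops))
        loop_lens = [config.loop_min + int(e) for e in extra]

        side = "o" if has_sp else str(rng.choice(["i", "o"]))
        parts: list[str] = ["S" * sp]
        is_helix = kind in ("alpha_single", "alpha_multi")
        for k in range(n_tm):
            parts.append(side * loop_lens[k])
            if side == "i":
                parts.append(("H" if is_helix else "B") * tm_lens[k])
                side = "o"
            else:
                parts.append(("h" if is_helix else "b") * tm_lens[k])
                side = "i"
        parts.append(side * loop_lens[-1])
        return parse_labels("".join(parts))
    raise RuntimeError(
        f"could not fit a {kind} topology into length range {config.length_range} "
        "after 100 attempts"
    )


def class_centroids(config: GeneratorConfig) -> np.ndarray:
    """Five fixed class mean vectors, seeded by the config seed.

    Random directions in D dimensions (near-orthogonal for moderate D) scaled
    to radius class_separation / sqrt(2), so that the expected distance
    between two centroids is about class_separation.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5EED]))
    v = rng.normal(size=(5, config.feature_dim))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return v * (config.class_separation / np.sqrt(2.0))


def sample_features(rng: np.random.Generator, labels: LabelSequence | str,
                    config: GeneratorConfig = GeneratorConfig(),
                    centroids: np.ndarray | None = None) -> np.ndarray:
    """Noisy class-centroid features with local context smoothing.

    Residue t gets centroid(class(t)) + N(0, noise_sd) in each of D
    dimensions (orientation case collapsed to the five observable classes);
    a moving average of half-width ``context_smoothing`` along the sequence
    then mimics the local context mixing of real embeddings.
    """
    s = labels.labels if isinstance(labels, LabelSequence) else labels
    if centroids is None:
        centroids = class_centroids(config)
    classes = np.array([CLASS_INDEX[c.upper() if c in "bh" else c] for c in s])
    X = centroids[classes] + rng.normal(0.0, config.noise_sd, size=(len(s), config.feature_dim))
    w = config.context_smoothing
    if w > 0:
        kernel = np.ones(2 * w + 1) / (2 * w + 1)
        from scipy.ndimage import convolve1d

        X = convolve1d(X, kernel, axis=0, mode="nearest")
    return X


def generate_dataset(n: int, config: GeneratorConfig = GeneratorConfig(),
                     out_dir: str | Path | None = None
                     ) -> tuple[list[SyntheticProtein], dict]:
    """Generate ``n`` proteins with the configured group mix.

    Group counts follow the mix proportions by largest remainder.  With
    ``out_dir`` the dataset is written through :mod:`memtop.io_formats` as
    ``proteins.fasta``, ``features.h5``, ``labels.txt`` and a
    ``manifest.yaml`` recording the seed and config.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(config.seed)
    centroids = class_centroids(config)

    raw = np.array(config.mix) * n
    counts = np.floor(raw).astype(int)
    order = np.argsort(-(raw - counts))
    for k in range(n - counts.sum()):
        counts[order[k]] += 1

    proteins: list[SyntheticProtein] = []
    idx = 0
    for (kind, has_sp), cnt in zip(GROUPS, counts):
        for _ in range(cnt):
            labels = sample_topology(rng, kind, has_sp, config)
            seq = "".join(rng.choice(list(_AA), size=len(labels)))
            rec = ProteinRecord(f"syn{idx:05d}", seq)
            feats = sample_features(rng, labels, config, centroids)
            proteins.append(SyntheticProtein(rec, labels, feats, (kind, has_sp)))
            idx += 1

    cfg_dict = asdict(config)
    manifest = {
        "n": n,
        "seed": config.seed,
        "config": cfg_dict,
        "config_hash": f"{hash(tuple(sorted((k, str(v)) for k, v in cfg_dict.items()))) & 0xFFFFFFFF:08x}",
        "group_counts": {f"{kind}{'+sp' if sp else ''}": int(c)
                         for (kind, sp), c in zip(GROUPS, counts)},
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(out / "proteins.fasta", [p.record for p in proteins])
        write_feature_container(out / "features.h5", {p.record.id: p.features for p in proteins})
        write_labels(out / "labels.txt", {p.record.id: p.labels for p in proteins})
        import yaml

        with open(out / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=False)
    return proteins, manifest
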