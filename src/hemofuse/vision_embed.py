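"""Toy vision-transformer image encoder and the pufferfish patch-size
optimizer.

The encoder is deliberately small and CPU-friendly: non-overlapping
patches, a shared linear projection with per-vector standardization, a
learnable-shaped CLS token and positional table, and a stack of
self-attention + MLP blocks.  All parameters are frozen seeded random
draws — at this scale the encoder acts as a random-feature extractor and
only downstream classifier heads are trained.

The pufferfish optimizer (POA) searches a small discrete set of candidate
patch sizes: a population of candidates moves toward the best-so-far
solution (exploration) and away from the worst-fitness "predator"
position (evasion), with continuous positions snapped back onto the
candidate grid.  Lower fitness is better.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PatchConfig",
    "POAConfig",
    "EncoderParams",
    "AttentionBlockParams",
    "patchify",
    "assemble_patches",
    "project_and_norm",
    "add_cls_and_positions",
    "multi_head_self_attention",
    "encode_image",
    "poa_optimize",
]

_NORM_EPS = 1e-8


@dataclass(frozen=True)
class PatchConfig:
    """Shape of the toy encoder.  Image sides must be divisible by
    patch_size and embed_dim by n_heads."""

    patch_size: int = 8
    embed_dim: int = 32
    n_heads: int = 4
    n_layers: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patch_size < 1:
            raise ValueError("patch_size must be positive")
        if self.embed_dim % self.n_heads != 0:
            raise ValueError(
                f"embed_dim {self.embed_dim} not divisible by n_heads {self.n_heads}"
            )


@dataclass
class AttentionBlockParams:
    wq: np.ndarray
    wk: np.ndarray
    wv: np.ndarray
    wo: np.ndarray
    w1: np.ndarray
    w2: np.ndarray
    n_heads: int = 1


@dataclass
class EncoderParams:
    patch_weights: np.ndarray  # (P*P, D)
    cls_vector: np.ndarray  # (D,)
    position_table: np.ndarray  # (N+1, D)
    blocks: list[AttentionBlockParams] = field(default_factory=list)


def patchify(image: np.ndarray, patch_size: int) -> np.ndarray:
    """Split an HxW image into N=(H/P)*(W/P) non-overlapping PxP patches in
    row-major order; concatenating them back reconstructs the image."""
    img = np.asarray(image)
    h, w = img.shape
    p = patch_size
    if h % p or w % p:
        raise ValueError(f"image dims {h}x{w} not divisible by patch size {p}")
    return (
        img.reshape(h // p, p, w // p, p)
        .transpose(0, 2, 1, 3)
        .reshape((h // p) * (w // p), p, p)
    )


def assemble_patches(patches: np.ndarray, image_shape: tuple[int, int]) -> np.ndarray:
    """Inverse of patchify."""
    h, w = image_shape
    n, p, _ = patches.shape
    return (
        patches.reshape(h // p, w // p, p, p).transpose(0, 2, 1, 3).reshape(h, w)
    )


def project_and_norm(patches: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Flatten each patch, apply the shared linear map, then standardize
    each vector to mean 0 / sd 1.  Zero-variance vectors map to zeros."""
    flat = np.asarray(patches, dtype=float).reshape(patches.shape[0], -1)
    if flat.shape[1] != weights.shape[0]:
        raise ValueError(
            f"patch dim {flat.shape[1]} incompatible with weight shape {weights.shape}"
        )
    proj = flat @ weights
    mean = proj.mean(axis=1, keepdims=True)
    sd = proj.std(axis=1, keepdims=True)
    out = np.where(sd > _NORM_EPS, (proj - mean) / np.maximum(sd, _NORM_EPS), 0.0)
    return out


def add_cls_and_positions(
    seq: np.ndarray, cls_vector: np.ndarray, position_table: np.ndarray
) -> np.ndarray:
    """Prepend the CLS vector and add the positional table elementwise."""
    n, d = seq.shape
    if position_table.shape[0] != n + 1:
        raise ValueError(
            f"position table has {position_table.shape[0]} rows, expected {n + 1}"
        )
    out = np.vstack([cls_vector[None, :], seq])
    return out + position_table


def _softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def multi_head_self_attention(
    seq: np.ndarray,
    params: AttentionBlockParams,
    return_weights: bool = False,
):
    """One encoder block: multi-head scaled dot-product self-attention with
    residual, then a ReLU MLP with residual.

    Attention rows are softmax-normalized (row-stochastic).  NaN inputs are
    rejected.  With ``return_weights`` the per-head weight matrices and the
    raw attended values (concatenated heads, before the output projection
    and residual) are returned alongside the block output.
    """
    x = np.asarray(seq, dtype=float)
    if np.isnan(x).any():
        raise ValueError("NaN in attention input")
    t, d = x.shape
    h = params.n_heads
    dh = d // h
    q = (x @ params.wq).reshape(t, h, dh)
    k = (x @ params.wk).reshape(t, h, dh)
    v = (x @ params.wv).reshape(t, h, dh)
    logits = np.einsum("qhd,khd->hqk", q, k) / np.sqrt(dh)
    weights = _softmax(logits, axis=-1)  # (h, t, t), rows sum to 1
    attended = np.einsum("hqk,khd->qhd", weights, v).reshape(t, d)
    out = x + attended @ params.wo
    out = out + np.maximum(out @ params.w1, 0.0) @ params.w2
    if return_weights:
        return out, weights, attended
    return out


def _init_params(config: PatchConfig, n_patches: int) -> EncoderParams:
    # Frozen random features: projection scaled ~1/sqrt(fan_in), attention
    # weights ~1/sqrt(D) so logits vary enough for content-dependent mixing.
    rng = np.random.default_rng([config.seed & 0x7FFFFFFF, 0x7E5])
    d = config.embed_dim
    p2 = config.patch_size**2
    params = EncoderParams(
        patch_weights=rng.normal(0.0, 1.0 / np.sqrt(p2), (p2, d)),
        cls_vector=rng.normal(0.0, 1.0, d),
        position_table=rng.normal(0.0, 1.0, (n_patches + 1, d)),
    )
    scale = 1.0 / np.sqrt(d)
    for _ in range(config.n_layers):
        params.blocks.append(
            AttentionBlockParams(
                wq=rng.normal(0.0, scale, (d, d)),
                wk=rng.normal(0.0, scale, (d, d)),
                wv=rng.normal(0.0, scale, (d, d)),
                wo=rng.normal(0.0, scale, (d, d)),
                w1=rng.normal(0.0, scale, (d, 4 * d)),
                w2=rng.normal(0.0, scale, (4 * d, d)),
                n_heads=config.n_heads,
            )
        )
    return params


def encode_image(
    image: np.ndarray, config: PatchConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Encode an image: patchify -> project+standardize -> CLS+positions ->
    attention blocks.  Returns (cls_embedding, patch_embeddings); fully
    deterministic for a fixed seed."""
    patches = patchify(image, config.patch_size)
    params = _init_params(config, patches.shape[0])
    seq = project_and_norm(patches, params.patch_weights)
    seq = add_cls_and_positions(seq, params.cls_vector, params.position_table)
    for block in params.blocks:
        seq = multi_head_self_attention(seq, block)
        # re-standardize between blocks to keep activations bounded
        mean = seq.mean(axis=1, keepdims=True)
        sd = seq.std(axis=1, keepdims=True)
        seq = np.where(sd > _NORM_EPS, (seq - mean) / np.maximum(sd, _NORM_EPS), 0.0)
    return seq[0], seq[1:]


# ---------------------------------------------------------------------------
# Pufferfish optimization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class POAConfig:
    """Population metaheuristic over a discrete candidate set.

    alpha is the evasion coefficient (move away from the worst "predator"
    position), beta the exploration coefficient (move toward the best).
    The population is initialized spread across the candidate set so every
    candidate is evaluated when population_size >= len(candidates).
    """

    candidate_patch_sizes: tuple[int, ...] = (4, 8, 16, 32)
    population_size: int = 8
    n_iterations: int = 10
    alpha: float = 0.5
    beta: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.candidate_patch_sizes:
            raise ValueError("candidate set is empty")
        if self.population_size < 2 and len(self.candidate_patch_sizes) > 1:
            raise ValueError("population_size must be >= 2")
        if not (0 < self.alpha <= 1 and 0 < self.beta <= 1):
            raise ValueError("alpha and beta must lie in (0, 1]")


def poa_optimize(fitness, config: POAConfig) -> tuple[int, list[float]]:
    """Minimize ``fitness`` over the candidate set; returns the best-ever
    candidate and the per-iteration best-so-far fitness history
    (non-increasing by elitism)."""
    candidates = np.asarray(sorted(set(config.candidate_patch_sizes)), dtype=float)
    if candidates.size == 1:
        only = int(candidates[0])
        return only, [float(fitness(only))]

    rng = np.random.default_rng(config.seed & 0x7FFFFFFF)
    cache: dict[int, float] = {}

    def eval_snapped(x: float) -> tuple[int, float]:
        snapped = int(candidates[np.argmin(np.abs(candidates - x))])
        if snapped not in cache:
            cache[snapped] = float(fitness(snapped))
        return snapped, cache[snapped]

    # diverse initialisation: permute candidates, cycle to fill the population
    perm = rng.permutation(candidates)
    positions = np.array(
        [perm[i % perm.size] for i in range(config.population_size)], dtype=float
    )
    fits = np.array([eval_snapped(x)[1] for x in positions])
    best_idx = int(np.argmin(fits))
    best_pos, best_fit = float(positions[best_idx]), float(fits[best_idx])
    history: list[float] = []

    for _ in range(config.n_iterations):
        worst_pos = float(positions[int(np.argmax(fits))])
        for i in range(len(positions)):
            r1, r2 = rng.uniform(0, 1, 2)
            positions[i] = (
                positions[i]
                + config.beta * r1 * (best_pos - positions[i])
                - config.alpha * r2 * (worst_pos - positions[i])
            )
            snapped, fit = eval_snapped(positions[i])
            fits[i] = fit
            if fit < best_fit:
                best_fit, best_pos = fit, float(snapped)
        history.append(best_fit)
    best_candidate = int(candidates[np.argmin(np.abs(candidates - best_pos))])
    return best_candidate, history
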