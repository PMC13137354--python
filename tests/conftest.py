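import numpy as np
import pytest

from hemofuse.synthetic_data import PhantomSpec


@pytest.fixture
def quiet_phantom() -> PhantomSpec:
    """Noise-free phantom spec: deterministic intensities everywhere."""
    return PhantomSpec(noise_sigma=0.0, seed=7)


@pytest.fixture
def noisy_phantom() -> PhantomSpec:
    """Default-texture phantom spec."""
    return PhantomSpec(noise_sigma=8.0, seed=11)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def brute_force_disc_area(center, radius, shape) -> int:
    """Independent pixel-by-pixel disc rasterizer used as an area oracle."""
    count = 0
    for r in range(shape[0]):
        for c in range(shape[1]):
            if (r - center[0]) ** 2 + (c - center[1]) ** 2 <= radius**2:
                count += 1
    return count


def brute_force_bilinear(image, tiles):
    """Per-pixel four-neighbor LUT blend, written independently of the
    vectorized implementation."""
    n_rows, n_cols = len(tiles), len(tiles[0])
    row_centers = [(t.tile_bounds[0] + t.tile_bounds[2] - 1) / 2.0 for t in (row[0] for row in tiles)]
    col_centers = [(t.tile_bounds[1] + t.tile_bounds[3] - 1) / 2.0 for t in tiles[0]]
    L = tiles[0][0].lut.size
    out = np.zeros_like(image, dtype=float)
    for r in range(image.shape[0]):
        for c in range(image.shape[1]):
            v = int(image[r, c])
            # fractional tile coordinates, clamped to edge centers
            if r <= row_centers[0]:
                i0, i1, wr = 0, 0, 0.0
            elif r >= row_centers[-1]:
                i0, i1, wr = n_rows - 1, n_rows - 1, 0.0
            else:
                i0 = max(i for i in range(n_rows) if row_centers[i] <= r)
                i1 = i0 + 1
                wr = (r - row_centers[i0]) / (row_centers[i1] - row_centers[i0])
            if c <= col_centers[0]:
                j0, j1, wc = 0, 0, 0.0
            elif c >= col_centers[-1]:
                j0, j1, wc = n_cols - 1, n_cols - 1, 0.0
            else:
                j0 = max(j for j in range(n_cols) if col_centers[j] <= c)
                j1 = j0 + 1
                wc = (c - col_centers[j0]) / (col_centers[j1] - col_centers[j0])
            out[r, c] = (
                (1 - wr) * (1 - wc) * tiles[i0][j0].lut[v]
                + (1 - wr) * wc * tiles[i0][j1].lut[v]
                + wr * (1 - wc) * tiles[i1][j0].lut[v]
                + wr * wc * tiles[i1][j1].lut[v]
            )
    return np.clip(np.round(out), 0, L - 1).astype(image.dtype)


def mann_whitney_auc(scores, labels) -> float:
    """AUC by exhaustive positive-negative pair counting (ties count 1/2)."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def exhaustive_segmentations(word, vocab):
    """All valid WordPiece segmentations of a word (DFS oracle)."""
    results = []

    def rec(start, pieces):
        if start == len(word):
            results.append(list(pieces))
            return
        prefix = "##" if start > 0 else ""
        for end in range(start + 1, len(word) + 1):
            cand = prefix + word[start:end]
            if cand in vocab:
                pieces.append(cand)
                rec(end, pieces)
                pieces.pop()

    rec(0, [])
    return results
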