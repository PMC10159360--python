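"""Fixed spatial basis sets (DCT, PCA) for basis-constrained encoding models.

Constraining the spatial convolutional filters to a truncated orthonormal
basis is a low-pass filtering control: it tests how much of the benefit of
normative regularization is explained by simple smoothing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

__all__ = ["BasisSet", "make_dct_basis", "make_pca_basis", "zigzag_order"]


@dataclass
class BasisSet:
    """An ordered set of orthonormal basis images.

    DCT bases are per-channel, shape [k, N, N] (each chromatic channel gets
    its own weights); PCA bases are channel-joint, shape [k, C, N, N].
    """

    basis: np.ndarray
    kind: str  # "dct" | "pca"
    eigenvalues: np.ndarray | None = None

    @property
    def k(self) -> int:
        return self.basis.shape[0]

    def flat(self) -> np.ndarray:
        return self.basis.reshape(self.k, -1)


def zigzag_order(n: int) -> list[tuple[int, int]]:
    """JPEG-style zig-zag traversal of an n-by-n index grid.

    Starts (0,0), (0,1), (1,0), (2,0), (1,1), (0,2), ...: anti-diagonals of
    increasing total index, walked downward on odd diagonals and upward on
    even ones.
    """
    order = []
    for s in range(2 * n - 1):
        if s % 2:  # odd: walk from top-right to bottom-left
            u_range = range(max(0, s - n + 1), min(s, n - 1) + 1)
        else:      # even: walk from bottom-left to top-right
            u_range = range(min(s, n - 1), max(0, s - n + 1) - 1, -1)
        order.extend((u, s - u) for u in u_range)
    return order


def make_dct_basis(n: int, k: int) -> BasisSet:
    """First k two-dimensional DCT-II basis images of size n-by-n.

    F_uv(i, j) = a(u) a(v) cos[(2i+1)pi u / 2n] cos[(2j+1)pi v / 2n] with
    a(0) = sqrt(1/n) and a(u>0) = sqrt(2/n); bases are returned in zig-zag
    order of (u, v), so low spatial frequencies come first.
    """
    if not 1 <= k <= n * n:
        raise ValueError(f"k must lie in [1, {n * n}]")
    i = np.arange(n)
    alpha = np.full(n, np.sqrt(2.0 / n))
    alpha[0] = np.sqrt(1.0 / n)
    cos = np.cos((2 * i[None, :] + 1) * np.pi * i[:, None] / (2 * n))  # [u, i]
    basis = np.empty((k, n, n))
    for idx, (u, v) in enumerate(zigzag_order(n)[:k]):
        basis[idx] = alpha[u] * alpha[v] * np.outer(cos[u], cos[v])
    return BasisSet(basis=basis, kind="dct")


def extract_patches(images: np.ndarray, patch: int, max_per_image: int | None = None,
                    seed: int = 0) -> np.ndarray:
    """Dense stride-1 patches [n_patches, C, patch, patch] from a corpus."""
    n, c, h, w = images.shape
    out_h, out_w = h - patch + 1, w - patch + 1
    view = np.lib.stride_tricks.sliding_window_view(images, (patch, patch), axis=(2, 3))
    patches = view.reshape(n, c, out_h * out_w, patch, patch)
    patches = patches.transpose(0, 2, 1, 3, 4).reshape(n * out_h * out_w, c, patch, patch)
    if max_per_image is not None and patches.shape[0] > n * max_per_image:
        rng = np.random.default_rng(seed)
        sel = rng.choice(patches.shape[0], size=n * max_per_image, replace=False)
        patches = patches[sel]
    return patches


def make_pca_basis(corpus, k: int, patch: int = 9) -> BasisSet:
    """Top-k principal components of channel-joint patches from a corpus.

    Rows of the returned basis are the eigenvectors of the centered patch
    covariance in descending eigenvalue order (W = U^T).  If the patch
    covariance has rank < k, the available components are returned and the
    shortfall is reflected in `k`.
    """
    images = corpus.images if hasattr(corpus, "images") else np.asarray(corpus)
    patches = extract_patches(images, patch)
    if patches.shape[0] < k:
        raise ValueError("corpus provides fewer patches than requested components")
    c = patches.shape[1]
    flat = patches.reshape(patches.shape[0], -1)
    n_comp = min(k, flat.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full")
    pca.fit(flat)
    keep = pca.explained_variance_ > 1e-12 * pca.explained_variance_[0]
    basis = pca.components_[keep].reshape(-1, c, patch, patch)
    return BasisSet(basis=basis, kind="pca", eigenvalues=pca.explained_variance_[keep])
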