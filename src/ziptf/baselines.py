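"""Thin adapters to external baseline factorizations for comparisons.

These wrap third-party implementations so their gene factors can be scored
with :mod:`ziptf.evaluation`; none of them is reimplemented here.  Each
adapter raises ``ImportError`` when its backing package is absent, and
comparative analyses simply skip the missing methods.
"""

from __future__ import annotations

import numpy as np

from .tensors import CountTensor

__all__ = ["nmf_gene_factors", "nncp_als_factors"]


def nmf_gene_factors(
    matrix: np.ndarray, rank: int, max_iter: int = 1000, seed: int = 0
) -> np.ndarray:
    """Genes x rank components from scikit-learn NMF on a cells x genes matrix."""
    from sklearn.decomposition import NMF

    model = NMF(n_components=rank, init="nndsvda", max_iter=max_iter,
                random_state=seed)
    model.fit_transform(np.asarray(matrix, dtype=float))
    return model.components_.T  # genes x rank


def nncp_als_factors(x: CountTensor, rank: int, seed: int = 0):
    """Non-negative CP via alternating least squares (requires tensorly)."""
    import tensorly as tl
    from tensorly.decomposition import non_negative_parafac_hals

    _, factors = non_negative_parafac_hals(
        tl.tensor(x.data), rank=rank, init="random", random_state=seed
    )
    return [np.asarray(f) for f in factors]
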