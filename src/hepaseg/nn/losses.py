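"""Per-voxel two-class cross-entropy on probability outputs."""

from __future__ import annotations

import numpy as np

_EPS = 1e-7


def sparse_categorical_crossentropy(probs: np.ndarray, labels: np.ndarray
                                    ) -> tuple[float, np.ndarray]:
    """Mean voxel-wise negative log-likelihood and its gradient w.r.t. ``probs``.

    ``probs`` has a trailing class axis summing to 1; ``labels`` holds integer
    class ids with the same leading shape.  The gradient is fed to the
    network's softmax node, which converts it into the usual ``p - onehot``
    logit gradient.
    """
    labels = np.asarray(labels).astype(np.int64)
    if labels.shape != probs.shape[:-1]:
        raise ValueError(f"labels shape {labels.shape} does not match probs {probs.shape[:-1]}")
    p = np.clip(probs, _EPS, 1.0)
    picked = np.take_along_axis(p, labels[..., None], axis=-1)[..., 0]
    n = labels.size
    loss = float(-np.log(picked).mean())
    gprobs = np.zeros_like(probs)
    np.put_along_axis(gprobs, labels[..., None], (-1.0 / (picked * n))[..., None], axis=-1)
    return loss, gprobs
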