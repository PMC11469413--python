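"""Synthetic sequence tasks for desk-scale BPTT training demos.

Both tasks stress retention over the full sequence length:

* ``delayed-recall`` — a one-hot token (4 classes) is shown at the first
  step, followed by zero input corrupted with small Gaussian noise
  (sd 0.05); the label is the initial token, recalled at the end.
* ``sequence-sum-sign`` — scalar inputs uniform on [−1, 1]; the label is
  the sign of their running sum (2 classes).
"""

from __future__ import annotations

import numpy as np

__all__ = ["make_task", "TASKS"]

TASKS = ("delayed-recall", "sequence-sum-sign")


def make_task(task: str, n_examples: int, seq_len: int,
              rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Generate (X, labels, n_classes, m) with X of shape (examples, T, m)."""
    if task == "delayed-recall":
        n_classes = 4
        m = n_classes
        labels = rng.integers(0, n_classes, n_examples)
        X = rng.normal(0.0, 0.05, (n_examples, seq_len, m))
        X[np.arange(n_examples), 0, labels] += 1.0
        return X, labels, n_classes, m
    if task == "sequence-sum-sign":
        X = rng.uniform(-1.0, 1.0, (n_examples, seq_len, 1))
        labels = (X.sum(axis=(1, 2)) > 0).astype(int)
        return X, labels, 2, 1
    raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")
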