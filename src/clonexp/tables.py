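"""Observed clonotype count-pair tables, the unit of all likelihoods."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["PairTable"]


class PairTable:
    """A table of clonotype count pairs ``(n, n')`` from two samples.

    The two samples are either same-day replicates (null inference) or two
    time points (expansion inference).  Every row must have ``n + n' > 0``:
    clones unseen in both samples are not observable and the likelihoods
    condition on their absence.

    The table caches the multiplicity index of unique ``(n, n')`` pairs,
    which all likelihood evaluations loop over instead of individual clones.
    """

    def __init__(self, clone_ids, n, n_prime):
        n = np.asarray(n)
        n_prime = np.asarray(n_prime)
        clone_ids = np.asarray(clone_ids, dtype=object)
        if not (len(clone_ids) == len(n) == len(n_prime)):
            raise ValueError("clone_ids, n, n_prime must have equal length")
        for arr, name in ((n, "n"), (n_prime, "n_prime")):
            if not np.issubdtype(arr.dtype, np.integer):
                if np.any(arr != np.floor(arr)):
                    raise ValueError(f"{name} contains non-integer counts")
            if np.any(arr < 0):
                raise ValueError(f"{name} contains negative counts")
        n = n.astype(np.int64)
        n_prime = n_prime.astype(np.int64)
        bad = n + n_prime == 0
        if np.any(bad):
            raise ValueError(
                f"{int(bad.sum())} rows have n + n' = 0; pair tables contain "
                "observed clones only (every row needs n + n' > 0)"
            )
        if len(set(clone_ids)) != len(clone_ids):
            raise ValueError("duplicate clone_id values")
        self.df = pd.DataFrame({"clone_id": clone_ids, "n": n, "n_prime": n_prime})
        self.n_reads = (int(n.sum()), int(n_prime.sum()))
        pairs, inverse, counts = np.unique(
            np.column_stack([n, n_prime]), axis=0, return_inverse=True, return_counts=True
        )
        self.unique_pairs = pairs  # (U, 2)
        self.pair_counts = counts  # multiplicity of each unique pair
        self.pair_index = inverse.ravel()  # row -> unique-pair index

    @classmethod
    def from_counts(cls, n, n_prime, prefix: str = "clone") -> "PairTable":
        ids = np.array([f"{prefix}{i}" for i in range(len(n))], dtype=object)
        return cls(ids, n, n_prime)

    @property
    def n_obs(self) -> int:
        return len(self.df)

    def __len__(self) -> int:
        return len(self.df)

    def __repr__(self) -> str:
        return (
            f"PairTable(n_obs={self.n_obs}, n_reads={self.n_reads}, "
            f"unique_pairs={len(self.unique_pairs)})"
        )
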