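"""Container for retained posterior draws with provenance."""
from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["PosteriorDraws"]


class PosteriorDraws:
    """Retained MCMC draws indexed by (chain, iteration, parameter name).

    Parameters
    ----------
    values : ndarray, shape (n_chains, n_draws, n_params)
    names : sequence of str
        Parameter names, in column order.
    schedule : ChainSchedule
        The chain schedule that produced the draws.
    seeds : sequence of int
        Per-chain seeds, for provenance.
    meta : dict, optional
        Backend metadata (e.g. acceptance rates).
    """

    def __init__(self, values, names, schedule=None, seeds=None, meta=None):
        self.values = np.asarray(values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must have shape (chains, draws, params)")
        self.names = tuple(names)
        if self.values.shape[2] != len(self.names):
            raise ValueError("parameter axis does not match names")
        self._index = {n: i for i, n in enumerate(self.names)}
        self.schedule = schedule
        self.seeds = tuple(seeds) if seeds is not None else None
        self.meta = dict(meta or {})

    @property
    def n_chains(self) -> int:
        return self.values.shape[0]

    @property
    def n_draws(self) -> int:
        return self.values.shape[1]

    def __contains__(self, name) -> bool:
        return name in self._index

    def get(self, name) -> np.ndarray:
        """Draws for one parameter, shape (n_chains, n_draws)."""
        try:
            return self.values[:, :, self._index[name]]
        except KeyError:
            raise KeyError(f"unknown parameter {name!r}") from None

    def stacked(self, name) -> np.ndarray:
        """All chains concatenated, shape (n_chains * n_draws,)."""
        return self.get(name).reshape(-1)

    def stacked_matrix(self) -> np.ndarray:
        """All draws pooled across chains, shape (n_chains*n_draws, n_params)."""
        return self.values.reshape(-1, len(self.names))

    @classmethod
    def from_dict(cls, mapping, **kwargs):
        """Build from {name: (chains, draws) array}; useful in tests."""
        names = list(mapping)
        arrs = [np.atleast_2d(np.asarray(mapping[n], dtype=float)) for n in names]
        values = np.stack(arrs, axis=-1)
        return cls(values, names, **kwargs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs):
        """Rebuild from the long-format export of :meth:`to_dataframe`."""
        chains = sorted(df["chain"].unique())
        names = [c for c in df.columns if c not in ("chain", "draw")]
        values = np.stack(
            [df.loc[df["chain"] == c, names].to_numpy() for c in chains]
        )
        return cls(values, names, **kwargs)

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format export: one row per (chain, draw), columns = parameters."""
        n_c, n_d, _ = self.values.shape
        df = pd.DataFrame(self.stacked_matrix(), columns=list(self.names))
        df.insert(0, "draw", np.tile(np.arange(n_d), n_c))
        df.insert(0, "chain", np.repeat(np.arange(n_c), n_d))
        return df

    def to_inferencedata(self):
        """Convert to an :class:`arviz.InferenceData` posterior group."""
        import arviz as az

        return az.from_dict(
            posterior={n: self.get(n) for n in self.names}
        )

    def subset(self, names) -> "PosteriorDraws":
        idx = [self._index[n] for n in names]
        return PosteriorDraws(
            self.values[:, :, idx], names, schedule=self.schedule,
            seeds=self.seeds, meta=self.meta,
        )
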