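"""Encoder layer: a grid of cortical columns producing sparse codes.

Each cortical column is a self-organizing map (SOM) of units over a random
subset of the front-end array (proximal afferents).  Units also carry a
bank of distal dendrites, each targeting a handful of units in one linked
neighbouring column; distal synapses grow under a spike-timing rule
(strengthen when the target fired one step earlier, weaken on simultaneous
firing) with periodic homeostatic normalization of each dendrite's weight
sum to at most one.

Activation per time step and column:

1. afferent Euclidean distances rank the units; the best ``proximal
   activation percentage`` of them form the excited cluster (deterministic
   ranking, or sampled with probability proportional to reciprocal
   distance when random behaviour is enabled);
2. dendrites whose summed weight onto previously active targets exceeds
   100 x the distal synaptic threshold count as active, giving each unit a
   distal support count;
3. distances are divided elementwise by support (zero support -> +inf) and
   the smallest-updated-distance units are collected, equality class by
   equality class, until at least the minimum active count is reached;
4. if that collection is the whole excited cluster (no contextual
   prediction), every excited unit fires -- a massive firing event (MFE);
   otherwise the collection is truncated to exactly the minimum active
   count, producing the sparse distributed representation.

Learning combines the static SOM update on proximal weights (independent
of which units fired) with the dynamic distal update above; inference mode
leaves every weight untouched.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

__all__ = [
    "TrainingSchedule",
    "EncoderConfig",
    "LayerActivation",
    "EncoderLayer",
    "initialize_layer",
    "sample_distinct",
    "choose_excited",
    "select_active",
    "normalize_dendrites",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class TrainingSchedule:
    """Stage/pass layout and learning-parameter decay.

    Within each stage the proximal learning rate, the distal rate scale and
    the SOM neighbourhood radius decay exponentially across passes; the
    exponential clock runs over global pass time and each stage applies an
    extra ``stage_decay`` factor, so stage-initial values shrink stage over
    stage and the whole profile decreases monotonically (no sawtooth at
    stage boundaries).  A final stage runs with the last stage's final
    parameters held fixed.
    """

    n_stages: int = 4
    passes_per_stage: int = 4
    final_passes: int = 4
    initial_learning_rate: float = 0.9
    initial_radius: float | None = None  # None -> half the unit-grid extent
    stage_decay: float = 0.5
    pass_decay_tau: float = 4.0

    def radius_default(self, unit_shape: tuple[int, int]) -> float:
        return max(unit_shape) / 2.0

    def passes(self, unit_shape: tuple[int, int]):
        """Yield one parameter record per pass (including the fixed stage)."""
        r0 = self.initial_radius if self.initial_radius is not None else self.radius_default(unit_shape)
        records = []
        for s in range(self.n_stages):
            for t in range(self.passes_per_stage):
                global_t = s * self.passes_per_stage + t
                decay = self.stage_decay**s * math.exp(-global_t / self.pass_decay_tau)
                records.append(
                    {
                        "stage": s,
                        "pass": t,
                        "learning_rate": self.initial_learning_rate * decay,
                        "radius": r0 * decay,
                        "distal_scale": decay,
                    }
                )
        fixed = dict(records[-1]) if records else {
            "learning_rate": self.initial_learning_rate, "radius": r0, "distal_scale": 1.0}
        for t in range(self.final_passes):
            records.append(
                {
                    "stage": self.n_stages,
                    "pass": t,
                    "learning_rate": fixed["learning_rate"],
                    "radius": fixed["radius"],
                    "distal_scale": fixed["distal_scale"],
                }
            )
        return records


@dataclass(frozen=True)
class EncoderConfig:
    """Architecture and dynamics of the encoder layer.

    Defaults reproduce the reference architecture: 15 x 15 columns of
    15 x 15 units over a 5 x 128 front-end array, 31 afferent samples per
    column, a 9 x 9 lateral receptive field with 90% of its columns linked,
    6 potential connections per dendrite, 99% sparsity and a 10% afferently
    excited cluster.
    """

    grid_shape: tuple[int, int] = (15, 15)
    unit_shape: tuple[int, int] = (15, 15)
    afferent_shape: tuple[int, int] = (5, 128)
    afferent_inputs: int = 31
    lateral_rf: tuple[int, int] = (9, 9)
    linked_fraction: float = 0.9
    potential_per_dendrite: int = 6
    sparsity: float = 0.99
    proximal_activation_pct: float = 0.10
    distal_synaptic_threshold: float = 0.001
    enable_random_behaviour: bool = True
    distal_normalization_period: int = 100
    persistent_total_responses: bool = False
    delta_plus: float = 0.01
    delta_minus: float = 0.005
    mfe_boost: float = 2.0
    schedule: TrainingSchedule = field(default_factory=TrainingSchedule)

    def __post_init__(self):
        if self.min_active_units < 1:
            raise ValueError("sparsity too high: minimum active units would be 0")
        if self.excited_count < self.min_active_units:
            raise ValueError("excited cluster smaller than the minimum active count")
        if self.n_linked > self.rf_size:
            raise ValueError("cannot link more columns than the receptive field holds")
        if self.lateral_rf[0] > self.grid_shape[0] or self.lateral_rf[1] > self.grid_shape[1]:
            raise ValueError("lateral receptive field larger than the column grid")
        if self.afferent_inputs > self.afferent_shape[0] * self.afferent_shape[1]:
            raise ValueError("more afferent inputs than front-end positions")

    @property
    def n_columns(self) -> int:
        return self.grid_shape[0] * self.grid_shape[1]

    @property
    def units_per_column(self) -> int:
        return self.unit_shape[0] * self.unit_shape[1]

    @property
    def min_active_units(self) -> int:
        return int((1.0 - self.sparsity) * self.units_per_column)

    @property
    def excited_count(self) -> int:
        return int(self.proximal_activation_pct * self.units_per_column)

    @property
    def rf_size(self) -> int:
        return self.lateral_rf[0] * self.lateral_rf[1]

    @property
    def n_linked(self) -> int:
        return int(self.linked_fraction * self.rf_size)

    @property
    def n_units_total(self) -> int:
        return self.n_columns * self.units_per_column

    @property
    def n_proximal_synapses(self) -> int:
        return self.n_units_total * self.afferent_inputs

    @property
    def n_distal_synapses(self) -> int:
        return self.n_units_total * self.distal_per_unit

    @property
    def distal_per_unit(self) -> int:
        return self.n_linked * self.potential_per_dendrite


@dataclass
class LayerActivation:
    """Per-column active unit sets plus the massive-firing flags."""

    active_mask: np.ndarray  # bool (C, U)
    mfe: np.ndarray  # bool (C,)
    t: int = 0

    @property
    def active_indices(self) -> list[np.ndarray]:
        return [np.flatnonzero(row) for row in self.active_mask]

    @property
    def counts(self) -> np.ndarray:
        return self.active_mask.sum(axis=1)


def sample_distinct(rng: np.random.Generator, n: int, shape: tuple, k: int) -> np.ndarray:
    """Draw ``k`` distinct integers from range(n) along the last axis."""
    if k > n:
        raise ValueError("cannot draw more distinct values than the range holds")
    total = int(np.prod(shape)) if shape else 1
    if k > n // 2 or total * n <= 5_000_000:
        keys = rng.random(shape + (n,))
        return np.argsort(keys, axis=-1)[..., :k].astype(np.int32)
    out = rng.integers(0, n, size=shape + (k,), dtype=np.int32)
    flat = out.reshape(-1, k)
    while True:
        s = np.sort(flat, axis=-1)
        dup = (s[:, 1:] == s[:, :-1]).any(axis=-1)
        bad = np.flatnonzero(dup)
        if bad.size == 0:
            break
        flat[bad] = rng.integers(0, n, size=(bad.size, k), dtype=np.int32)
    return out


def choose_excited(
    distances: np.ndarray, count: int, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Pick the afferently excited cluster for one column.

    Deterministic: the ``count`` smallest distances (ties by unit index).
    Stochastic: weighted sampling without replacement with probability
    proportional to the reciprocal distance.
    """
    U = len(distances)
    if count >= U:
        return np.arange(U)
    if rng is None:
        return np.argsort(distances, kind="stable")[:count]
    w = 1.0 / np.maximum(distances, 1e-300)
    keys = np.power(rng.random(U), 1.0 / w)  # Efraimidis-Spirakis reservoir keys
    return np.argsort(-keys, kind="stable")[:count]


def select_active(
    updated_distances: np.ndarray,
    excited: np.ndarray,
    min_active: int,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, bool]:
    """Collect the winners among the excited cluster (activation part 2).

    Equality classes of the updated distance are accumulated from the
    smallest value until at least ``min_active`` units are collected.  If
    that collection is the entire excited cluster the column fires
    massively (every excited unit active); otherwise the last class is
    truncated -- by stable order, or at random when ``rng`` is given -- so
    exactly ``min_active`` units fire.
    """
    vals = updated_distances[excited]
    E = len(excited)
    m = min(min_active, E)
    order = np.argsort(vals, kind="stable")
    sv = vals[order]
    j = m
    while j < E and sv[j] == sv[j - 1]:
        j += 1
    if j >= E:
        active = np.sort(excited)
        return active, len(active) > min_active
    lo = m - 1
    while lo > 0 and sv[lo - 1] == sv[lo]:
        lo -= 1
    tied = order[lo:j]
    if rng is not None:
        tied = rng.permutation(tied)
    chosen = np.concatenate([order[:lo], tied[: m - lo]])
    return np.sort(excited[chosen]), False


def normalize_dendrites(distal: np.ndarray, tol: float = 1.0) -> None:
    """Rescale, in place, every dendrite whose weight sum exceeds ``tol`` to sum 1."""
    sums = distal.sum(axis=-1, keepdims=True)
    np.divide(distal, sums, out=distal, where=sums > tol)


class EncoderLayer:
    """The trained object: column grid, weights, margins and RNG state."""

    def __init__(self, config: EncoderConfig, seed: int = 0):
        self.config = config
        self.seed = int(seed)
        ss = np.random.SeedSequence([self.seed, 0xE17C0])
        init_ss, run_ss = ss.spawn(2)
        rng = np.random.default_rng(init_ss)
        self.rng = np.random.default_rng(run_ss)

        C, U, A = config.n_columns, config.units_per_column, config.afferent_inputs
        L, K = config.n_linked, config.potential_per_dendrite
        n_positions = config.afferent_shape[0] * config.afferent_shape[1]

        # Afferent sampling: the wraparound receptive field covers the whole
        # front-end array, so every position is eligible for every column.
        self.afferent_idx = sample_distinct(rng, n_positions, (C,), A)
        self.proximal = rng.random((C, U, A))
        self.margin_min = np.full((C, A), np.inf)
        self.margin_max = np.full((C, A), -np.inf)

        # Lateral links: per column, a subset of its wraparound RF.
        rf_cols = self._rf_columns()  # (C, rf_size) column ids
        pick = sample_distinct(rng, config.rf_size, (C,), L)
        self.linked = np.take_along_axis(rf_cols, pick, axis=1).astype(np.int32)
        self.targets = sample_distinct(rng, U, (C, U, L), K)
        self.distal = np.zeros((C, U, L, K), dtype=np.float64)

        self.total_responses = np.zeros((C, U))
        self._updated_step = 0
        self._prev_active: np.ndarray | None = None
        self._t = 0

        # unit-grid Manhattan distances for the SOM neighbourhood kernel
        gy, gx = np.unravel_index(np.arange(U), config.unit_shape)
        self._unit_manhattan = np.abs(gy[:, None] - gy[None, :]) + np.abs(gx[:, None] - gx[None, :])

    def _rf_columns(self) -> np.ndarray:
        """Wraparound lateral receptive field: (C, rf_size) neighbour ids."""
        gr, gc = self.config.grid_shape
        hr, hc = self.config.lateral_rf[0] // 2, self.config.lateral_rf[1] // 2
        ci, cj = np.unravel_index(np.arange(self.config.n_columns), (gr, gc))
        di = np.arange(-hr, self.config.lateral_rf[0] - hr)
        dj = np.arange(-hc, self.config.lateral_rf[1] - hc)
        ni = (ci[:, None, None] + di[None, :, None]) % gr
        nj = (cj[:, None, None] + dj[None, None, :]) % gc
        return (ni * gc + nj).reshape(self.config.n_columns, -1)

    # ----- spec-level operations -------------------------------------------

    def gather_inputs(self, values: np.ndarray, undetermined: np.ndarray):
        """Extract each column's afferent sample from a front-end frame."""
        if values.shape != self.config.afferent_shape:
            raise ValueError(
                f"frame shape {values.shape} != afferent {self.config.afferent_shape}"
            )
        flat_v = values.reshape(-1)
        flat_u = undetermined.reshape(-1)
        return flat_v[self.afferent_idx], flat_u[self.afferent_idx]

    def impute_undetermined(
        self, x: np.ndarray, undet: np.ndarray, rng: np.random.Generator, learn: bool
    ) -> np.ndarray:
        """Fill undetermined components from each input's learned margins.

        Undetermined values are drawn uniformly between the running min/max
        observed for that afferent component ([0, 1] before any data).
        Margins update from determined components only while learning.
        """
        det = ~undet
        if learn and det.any():
            self.margin_min = np.where(det, np.minimum(self.margin_min, x), self.margin_min)
            self.margin_max = np.where(det, np.maximum(self.margin_max, x), self.margin_max)
        u = rng.random(x.shape)
        valid = self.margin_min <= self.margin_max
        lo = np.where(valid, self.margin_min, 0.0)
        hi = np.where(valid, self.margin_max, 1.0)
        return np.where(undet, lo + u * (hi - lo), x)

    def compute_distal_support(self, prev_active: np.ndarray | None):
        """Count, per unit, dendrites predicting from the previous activation.

        Returns (support (C, U) int, prev_target_mask (C, U, L, K) bool).
        A dendrite is active when the summed weight of its synapses onto
        previously active targets exceeds 100 x the distal threshold.
        """
        cfg = self.config
        C, U = cfg.n_columns, cfg.units_per_column
        if prev_active is None:
            mask = np.zeros(self.targets.shape, dtype=bool)
            support = np.zeros((C, U), dtype=np.int64)
        else:
            mask = prev_active[self.linked[:, None, :, None], self.targets]
            acc = (self.distal * mask).sum(axis=-1)
            support = (acc > 100.0 * cfg.distal_synaptic_threshold).sum(axis=-1)
        if cfg.persistent_total_responses:
            self.total_responses += support
            support = self.total_responses.astype(np.int64)
        return support, mask

    def _activate(self, distances, support, rng):
        """Run both activation parts for every column."""
        cfg = self.config
        C, U = distances.shape
        E, m = cfg.excited_count, cfg.min_active_units
        if cfg.enable_random_behaviour:
            w = 1.0 / np.maximum(distances, 1e-300)
            keys = np.power(rng.random((C, U)), 1.0 / w)
            excited = np.argsort(-keys, axis=1, kind="stable")[:, :E]
        else:
            excited = np.argsort(distances, axis=1, kind="stable")[:, :E]
        updated = np.divide(
            distances, support, out=np.full_like(distances, np.inf), where=support > 0
        )
        active_mask = np.zeros((C, U), dtype=bool)
        mfe = np.zeros(C, dtype=bool)
        sel_rng = rng if cfg.enable_random_behaviour else None
        # Vectorized fast paths; the per-column routine handles equality
        # classes straddling the cutoff (active sets identical either way).
        ud_exc = np.take_along_axis(updated, excited, axis=1)
        order = np.argsort(ud_exc, axis=1, kind="stable")
        sv = np.take_along_axis(ud_exc, order, axis=1)
        if E > m:
            all_tied = sv[:, 0] == sv[:, -1]  # incl. the no-context all-inf case
            clear_cut = ~all_tied & (sv[:, m] != sv[:, m - 1])
        else:
            all_tied = np.ones(C, dtype=bool)
            clear_cut = np.zeros(C, dtype=bool)
        if all_tied.any():
            rows = np.flatnonzero(all_tied)
            active_mask[np.repeat(rows, E), excited[rows].ravel()] = True
            mfe[rows] = E > m
        if clear_cut.any():
            rows = np.flatnonzero(clear_cut)
            chosen = np.take_along_axis(excited[rows], order[rows][:, :m], axis=1)
            active_mask[np.repeat(rows, m), chosen.ravel()] = True
        for c in np.flatnonzero(~(all_tied | clear_cut)):
            act, is_mfe = select_active(updated[c], excited[c], m, sel_rng)
            active_mask[c, act] = True
            mfe[c] = is_mfe
        return active_mask, mfe

    def ssom_update(self, x: np.ndarray, distances: np.ndarray, lr: float, radius: float):
        """SOM update of proximal weights (fires-independent plasticity)."""
        if lr <= 0:
            return
        bmu = np.argmin(distances, axis=1)  # (C,)
        d = self._unit_manhattan[bmu]  # (C, U)
        if radius > 0:
            h = np.exp(-0.5 * (d / radius) ** 2)
        else:
            h = (d == 0).astype(float)
        self.proximal += lr * h[:, :, None] * (x[:, None, :] - self.proximal)

    def dsom_update(
        self,
        active_mask: np.ndarray,
        mfe: np.ndarray,
        prev_mask: np.ndarray,
        distal_scale: float = 1.0,
    ):
        """STDP-like distal update plus periodic homeostatic normalization.

        For every currently active unit: synapses onto targets active in
        the previous step gain delta_plus (doubled during an MFE); synapses
        onto targets active now lose delta_minus (floored at zero).
        """
        cfg = self.config
        cols, units = np.nonzero(active_mask)
        if cols.size:
            lc = self.linked[cols]  # (n, L)
            tg = self.targets[cols, units]  # (n, L, K)
            cur_rows = active_mask[lc[:, :, None], tg]
            dplus = cfg.delta_plus * distal_scale * np.where(mfe[cols], cfg.mfe_boost, 1.0)
            sub = self.distal[cols, units]
            sub += dplus[:, None, None] * prev_mask[cols, units]
            sub -= (cfg.delta_minus * distal_scale) * cur_rows
            np.maximum(sub, 0.0, out=sub)
            self.distal[cols, units] = sub
        if self._updated_step >= cfg.distal_normalization_period:
            normalize_dendrites(self.distal)
            self._updated_step = 0
        self._updated_step += 1

    def step(
        self,
        values: np.ndarray,
        undetermined: np.ndarray | None = None,
        learn: bool = False,
        learning_rate: float = 0.1,
        radius: float = 1.0,
        distal_scale: float = 1.0,
        rng: np.random.Generator | None = None,
        prev_active: np.ndarray | None | str = "layer",
    ) -> LayerActivation:
        """Process one front-end frame and return the layer activation."""
        rng = self.rng if rng is None else rng
        if undetermined is None:
            undetermined = np.zeros_like(values, dtype=bool)
        x, undet = self.gather_inputs(values, undetermined)
        x = self.impute_undetermined(x, undet, rng, learn)
        distances = np.linalg.norm(self.proximal - x[:, None, :], axis=2)
        prev = self._prev_active if isinstance(prev_active, str) else prev_active
        support, prev_mask = self.compute_distal_support(prev)
        active_mask, mfe = self._activate(distances, support, rng)
        if learn:
            self.ssom_update(x, distances, learning_rate, radius)
            self.dsom_update(active_mask, mfe, prev_mask, distal_scale)
        if isinstance(prev_active, str):
            self._prev_active = active_mask
            self._t += 1
        return LayerActivation(active_mask=active_mask, mfe=mfe, t=self._t - 1)

    def reset_context(self):
        self._prev_active = None
        self.total_responses[:] = 0.0

    def train(self, stream, log: list | None = None) -> list[dict]:
        """Run the staged training schedule over a front-end stream.

        The stream is replayed once per pass; context carries across passes
        (the corpus ends in silence, so no spurious transition is learned).
        Returns the schedule log, one record per pass with the parameter
        values used and the pass's MFE rate.
        """
        records = self.config.schedule.passes(self.config.unit_shape)
        log = [] if log is None else log
        for rec in records:
            mfe_events = 0
            total = 0
            for t in range(len(stream)):
                act = self.step(
                    stream.values[t],
                    stream.undetermined[t],
                    learn=True,
                    learning_rate=rec["learning_rate"],
                    radius=rec["radius"],
                    distal_scale=rec["distal_scale"],
                )
                mfe_events += int(act.mfe.sum())
                total += len(act.mfe)
            log.append({**rec, "mfe_rate": mfe_events / max(total, 1)})
        return log

    def infer(self, stream, seed: int = 0) -> list[LayerActivation]:
        """Inference mode: activations only, no weight or margin changes.

        Uses a private RNG and context so the layer state is untouched and
        repeated calls with the same seed are identical.
        """
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 0x1FE2, int(seed)]))
        prev: np.ndarray | None = None
        out = []
        for t in range(len(stream)):
            act = self.step(
                stream.values[t],
                stream.undetermined[t],
                learn=False,
                rng=rng,
                prev_active=prev,
            )
            act.t = t
            prev = act.active_mask
            out.append(act)
        return out

    # ----- reporting --------------------------------------------------------

    def established_synapse_fraction(self) -> float:
        """Fraction of distal potential synapses above the synaptic threshold."""
        return float((self.distal > self.config.distal_synaptic_threshold).mean())

    def weight_checksum(self) -> tuple[float, float, float, float]:
        return (
            float(self.proximal.sum()),
            float(self.distal.sum()),
            float(np.where(np.isfinite(self.margin_min), self.margin_min, 0).sum()),
            float(np.where(np.isfinite(self.margin_max), self.margin_max, 0).sum()),
        )


def initialize_layer(config: EncoderConfig, seed: int = 0) -> EncoderLayer:
    return EncoderLayer(config, seed)


# ----- persistence ----------------------------------------------------------

def _config_to_json(config: EncoderConfig) -> str:
    d = dict(config.__dict__)
    d["schedule"] = dict(config.schedule.__dict__)
    return json.dumps(d)


def _config_from_json(text: str) -> EncoderConfig:
    d = json.loads(text)
    d["schedule"] = TrainingSchedule(**d["schedule"])
    for key in ("grid_shape", "unit_shape", "afferent_shape", "lateral_rf"):
        d[key] = tuple(d[key])
    return EncoderConfig(**d)


def save_model(path: str | Path, layer: EncoderLayer) -> None:
    with h5py.File(path, "w") as fh:
        fh.attrs["format"] = "cstm-encoder-v1"
        fh.attrs["config"] = _config_to_json(layer.config)
        fh.attrs["seed"] = layer.seed
        fh.attrs["updated_step"] = layer._updated_step
        fh.attrs["t"] = layer._t
        fh.attrs["rng_state"] = json.dumps(layer.rng.bit_generator.state)
        for name in ("afferent_idx", "proximal", "margin_min", "margin_max",
                     "linked", "targets", "distal", "total_responses"):
            fh.create_dataset(name, data=getattr(layer, name))
        if layer._prev_active is not None:
            fh.create_dataset("prev_active", data=layer._prev_active)


def load_model(path: str | Path) -> EncoderLayer:
    with h5py.File(path, "r") as fh:
        if fh.attrs.get("format") != "cstm-encoder-v1":
            raise ValueError(f"{path}: not a cstm encoder model file")
        config = _config_from_json(fh.attrs["config"])
        layer = EncoderLayer(config, seed=int(fh.attrs["seed"]))
        for name in ("afferent_idx", "proximal", "margin_min", "margin_max",
                     "linked", "targets", "distal", "total_responses"):
            setattr(layer, name, fh[name][...])
        layer._updated_step = int(fh.attrs["updated_step"])
        layer._t = int(fh.attrs["t"])
        layer.rng.bit_generator.state = json.loads(fh.attrs["rng_state"])
        layer._prev_active = fh["prev_active"][...] if "prev_active" in fh else None
    return layer
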