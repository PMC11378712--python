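"""Synthetic multi-participant datasets with the four paradigms' block
structure and known diffusion-process ground truth.

The generator reproduces the study design the pipeline expects — 10
experimental blocks of 122 trials plus a 22-trial practice block, two
warm-up trials per block, and paradigm-specific balancing — and draws each
trial's (RT, correctness) from a seven-parameter diffusion process whose
parameters depend on the trial's (stimulus type x sequence) cell.
Optional fast-guess and slow-lapse contaminants exercise the RT filters.
Because the generative parameters are known, every downstream stage
(filtering, sequence coding, descriptive and model-based fits, power) can
be tested for recovery without any external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffusion import DiffusionParams7, simulate_diffusion
from .preprocessing import (
    ALTERNATION,
    REPETITION,
    STIMULUS_TYPES,
    UNDEFINED,
    TrialTable,
    _pair_label,
)

#: default lower RT cutoffs (ms) used for fast-guess contaminant support
PARADIGM_CUTOFF_MS = {
    "visual_search": 300.0,
    "interference": 300.0,
    "two_choice": 250.0,
    "task_switching": 250.0,
}

_VS_TARGETS = (("color", "red_square"), ("color", "blue_square"),
               ("form", "green_triangle"), ("form", "green_circle"))
_INT_COLORS_ODD = ("red", "green")
_INT_COLORS_EVEN = ("orange", "blue")


@dataclass(frozen=True)
class DesignSpec:
    """Block/trial design: 10 experimental blocks x 122 trials plus a
    22-trial practice block; the first two trials of every block are
    warm-ups instantiating an alternation of the paradigm's critical
    feature."""

    paradigm: str
    n_blocks: int = 10
    trials_per_block: int = 122
    n_practice: int = 22
    n_warmup: int = 2

    def __post_init__(self) -> None:
        if self.paradigm not in STIMULUS_TYPES:
            raise ValueError(f"unknown paradigm {self.paradigm!r}")
        if self.trials_per_block <= self.n_warmup:
            raise ValueError("trials_per_block must exceed n_warmup")


@dataclass
class GroundTruth:
    """Generative parameters per (stimulus_type, sequence) cell plus
    contaminant settings.

    ``cells`` maps (stimulus_type, sequence) to a
    :class:`~rtseq.diffusion.DiffusionParams7`; trials whose sequence is
    undefined (block-initial trials, target-absent pairs) fall back to the
    alternation cell of their stimulus type.  Contaminant trials replace
    the diffusion outcome: fast guesses draw a uniform RT between 100 ms
    and the paradigm cutoff with a random response; slow lapses draw a
    uniform RT in (3000, 6000] ms, keeping the model response.
    """

    cells: dict[tuple[str, str], DiffusionParams7]
    fast_guess_rate: float = 0.0
    slow_lapse_rate: float = 0.0
    fast_guess_range_ms: tuple[float, float] = (100.0, 300.0)
    slow_lapse_range_ms: tuple[float, float] = (3000.0, 6000.0)
    seed: int | None = None

    def __post_init__(self) -> None:
        for r in (self.fast_guess_rate, self.slow_lapse_rate):
            if not (0 <= r <= 1):
                raise ValueError("contamination rates must be in [0, 1]")

    def lookup(self, stimulus_type: str, sequence: str) -> DiffusionParams7:
        key = (stimulus_type, sequence)
        if key in self.cells:
            return self.cells[key]
        fallback = (stimulus_type, ALTERNATION)
        if fallback in self.cells:
            return self.cells[fallback]
        raise KeyError(f"no ground-truth cell for {key}")

    def to_json(self) -> str:
        payload = {
            "cells": {
                f"{st}|{seq}": vars(p).copy() for (st, seq), p in self.cells.items()
            },
            "fast_guess_rate": self.fast_guess_rate,
            "slow_lapse_rate": self.slow_lapse_rate,
            "fast_guess_range_ms": list(self.fast_guess_range_ms),
            "slow_lapse_range_ms": list(self.slow_lapse_range_ms),
            "seed": self.seed,
        }
        return json.dumps(payload, indent=2)


def default_ground_truth(
    paradigm: str,
    delta_v: float = 0.5,
    delta_t0: float = 0.03,
    fast_guess_rate: float = 0.02,
    slow_lapse_rate: float = 0.01,
    seed: int | None = None,
) -> GroundTruth:
    """Study-condition defaults: a repetition advantage of ``delta_v`` in
    drift and ``delta_t0`` seconds in non-decision time on top of a base
    process (a = 1.5, v = 3.0, t0 = 0.33, w = 0.5, sigma_v = 1.0,
    sigma_w = 0.10, sigma_t0 = 0.08), magnitudes typical of fitted values
    in these paradigms; 2% fast guesses and 1% slow lapses."""
    base = dict(a=1.5, w=0.5, sigma_v=1.0, sigma_w=0.10, sigma_t0=0.08)
    cells: dict[tuple[str, str], DiffusionParams7] = {}
    for st in STIMULUS_TYPES[paradigm]:
        cells[(st, ALTERNATION)] = DiffusionParams7(v=3.0, t0=0.33, **base)
        cells[(st, REPETITION)] = DiffusionParams7(
            v=3.0 + delta_v, t0=0.33 - delta_t0, **base
        )
    cutoff = PARADIGM_CUTOFF_MS[paradigm]
    return GroundTruth(
        cells=cells,
        fast_guess_rate=fast_guess_rate,
        slow_lapse_rate=slow_lapse_rate,
        fast_guess_range_ms=(100.0, cutoff),
        seed=seed,
    )


def _block_body(paradigm: str, n: int, rng, positions_offset: int, strict: bool):
    """Balanced (stimulus_type, stimulus_detail) list for the non-warm-up
    part of a block.  ``positions_offset`` is the 1-based position of the
    first body trial, needed for the interference odd/even color scheme."""
    if paradigm == "visual_search":
        n_absent = int(round(0.4 * n))
        n_present = n - n_absent
        if strict and (n_absent != 0.4 * n or n_present % len(_VS_TARGETS)):
            raise ValueError("visual_search balancing needs 40/60 split and equal targets")
        per, rem = divmod(n_present, len(_VS_TARGETS))
        items = [("absent", "none")] * n_absent
        for st, detail in _VS_TARGETS:
            items += [(st, detail)] * per
        for i in rng.permutation(len(_VS_TARGETS))[:rem]:
            items.append(_VS_TARGETS[i])
        rng.shuffle(items)
        return items
    if paradigm == "two_choice":
        if strict and n % 2:
            raise ValueError("two_choice balancing needs an even count")
        half = n // 2
        items = [("majority_green", "green")] * half + [("majority_red", "red")] * (n - half)
        rng.shuffle(items)
        return items
    if paradigm == "interference":
        # odd positions use red/green, even positions orange/blue; each
        # color x congruency cell equally frequent
        n_odd = sum(1 for i in range(n) if (positions_offset + i) % 2 == 1)
        n_even = n - n_odd
        if strict and (n_odd % 4 or n_even % 4):
            raise ValueError("interference balancing needs counts divisible by 4 per parity")

        def cells(colors, m):
            combos = [(cong, c) for c in colors for cong in ("congruent", "incongruent")]
            per, rem = divmod(m, len(combos))
            base = []
            for combo in combos:
                base += [combo] * per
            for i in rng.permutation(len(combos))[:rem]:
                base.append(combos[i])
            return base

        odd_items = cells(_INT_COLORS_ODD, n_odd)
        even_items = cells(_INT_COLORS_EVEN, n_even)
        rng.shuffle(odd_items)
        rng.shuffle(even_items)
        out, oi, ei = [], 0, 0
        for i in range(n):
            if (positions_offset + i) % 2 == 1:
                out.append(odd_items[oi])
                oi += 1
            else:
                out.append(even_items[ei])
                ei += 1
        return out
    if paradigm == "task_switching":
        combos = [("color_task", "majority_green"), ("color_task", "majority_red"),
                  ("form_task", "majority_triangle"), ("form_task", "majority_circle")]
        if strict and n % len(combos):
            raise ValueError("task_switching balancing needs counts divisible by 4")
        per, rem = divmod(n, len(combos))
        items = []
        for c in combos:
            items += [c] * per
        for i in rng.permutation(len(combos))[:rem]:
            items.append(combos[i])
        rng.shuffle(items)
        return items
    raise ValueError(f"unknown paradigm {paradigm!r}")


def _warmups(paradigm: str, rng) -> list:
    """Two warm-up trials forming an alternation of the critical feature."""
    if paradigm == "visual_search":
        present = _VS_TARGETS[rng.integers(4)]
        pair = [("absent", "none"), present]
    elif paradigm == "two_choice":
        pair = [("majority_green", "green"), ("majority_red", "red")]
    elif paradigm == "interference":
        c_odd = _INT_COLORS_ODD[rng.integers(2)]
        c_even = _INT_COLORS_EVEN[rng.integers(2)]
        pair = [("congruent", c_odd), ("incongruent", c_even)]
        if rng.random() < 0.5:
            pair = [("incongruent", c_odd), ("congruent", c_even)]
        return pair  # order fixed by odd/even color scheme
    elif paradigm == "task_switching":
        pair = [("color_task", "majority_green"), ("form_task", "majority_circle")]
    else:
        raise ValueError(f"unknown paradigm {paradigm!r}")
    rng.shuffle(pair)
    return pair


def make_design(spec: DesignSpec, seed) -> list[list[tuple[str, str]]]:
    """Ordered (stimulus_type, stimulus_detail) sequences per block.

    Element 0 is the practice block (balanced as evenly as the practice
    length allows); elements 1..n_blocks are experimental blocks whose
    non-warm-up trials satisfy the paradigm's balancing exactly.
    Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    blocks = []
    for b in range(spec.n_blocks + 1):
        n_total = spec.n_practice if b == 0 else spec.trials_per_block
        body_n = n_total - spec.n_warmup
        body = _block_body(
            spec.paradigm, body_n, rng,
            positions_offset=spec.n_warmup + 1,
            strict=(b > 0),
        )
        blocks.append(_warmups(spec.paradigm, rng) + body)
    return blocks


def _correct_response(paradigm: str, stimulus_type: str) -> str:
    """Key label of the correct response (counterbalancing is metadata
    only; a fixed mapping is used)."""
    first = {
        "visual_search": ("absent",),
        "two_choice": ("majority_green",),
        "interference": ("congruent",),  # response follows central color; proxy label
        "task_switching": ("color_task",),
    }
    return "f" if stimulus_type in first[paradigm] else "j"


def simulate_dataset(
    spec: DesignSpec,
    truth: GroundTruth,
    n_participants: int,
    seed,
    dt: float = 0.0005,
) -> tuple[TrialTable, GroundTruth]:
    """Full synthetic dataset: realized designs per participant, per-trial
    diffusion outcomes from the trial's (stimulus type x sequence) cell,
    and contaminant replacement.  Returns the trial table and the ground
    truth used (for recovery tests)."""
    ss = np.random.SeedSequence(seed)
    rows = []
    for p, child in enumerate(ss.spawn(n_participants)):
        rng = np.random.default_rng(child)
        design = make_design(spec, rng.integers(2**31))
        # assign every trial to its generative cell using the same pairing
        # rules as preprocessing.code_sequence
        trial_meta = []  # (block, trial, stype, detail, cell_key)
        for b, block in enumerate(design):
            prev = None
            for i, (stype, detail) in enumerate(block, start=1):
                if prev is None:
                    seq = UNDEFINED
                else:
                    seq = _pair_label(
                        spec.paradigm,
                        {"stimulus_type": prev},
                        {"stimulus_type": stype},
                    )
                trial_meta.append((b, i, stype, detail, (stype, seq)))
                prev = stype
        # batch-simulate per cell
        by_cell: dict[tuple[str, str], list[int]] = {}
        for j, meta in enumerate(trial_meta):
            key = meta[4]
            params_key = key if key in truth.cells else (key[0], ALTERNATION)
            by_cell.setdefault(params_key, []).append(j)
        rt_s = np.empty(len(trial_meta))
        correct = np.empty(len(trial_meta), dtype=bool)
        for key, idx in by_cell.items():
            sim = simulate_diffusion(
                truth.lookup(*key), len(idx), seed=rng.integers(2**31), dt=dt
            )
            rt_s[idx] = sim.rt
            correct[idx] = sim.upper
        # contaminants
        u = rng.random(len(trial_meta))
        fast = u < truth.fast_guess_rate
        lapse = (~fast) & (u < truth.fast_guess_rate + truth.slow_lapse_rate)
        rt_ms = rt_s * 1000.0
        if fast.any():
            lo, hi = truth.fast_guess_range_ms
            rt_ms[fast] = rng.uniform(lo, hi, int(fast.sum()))
            correct[fast] = rng.random(int(fast.sum())) < 0.5
        if lapse.any():
            lo, hi = truth.slow_lapse_range_ms
            rt_ms[lapse] = rng.uniform(lo, hi, int(lapse.sum()))
        pid = f"p{p+1:03d}"
        for j, (b, i, stype, detail, _) in enumerate(trial_meta):
            resp = _correct_response(spec.paradigm, stype)
            if not correct[j]:
                resp = "j" if resp == "f" else "f"
            rows.append(
                (pid, spec.paradigm, b, i, stype, detail, resp, bool(correct[j]),
                 float(rt_ms[j]))
            )
    df = pd.DataFrame(
        rows,
        columns=["participant", "paradigm", "block", "trial", "stimulus_type",
                 "stimulus_detail", "response", "correct", "rt_ms"],
    )
    table = TrialTable(
        df,
        n_blocks=spec.n_blocks,
        trials_per_block=spec.trials_per_block,
        n_warmup_per_block=spec.n_warmup,
    )
    return table, truth
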