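"""Logging setup and deterministic seed-stream derivation."""

from __future__ import annotations

import logging
import sys

import numpy as np

__all__ = ["get_logger", "setup_logging", "child_seed", "child_rng"]

_LOGGER_NAME = "gemcov"


def get_logger(name: str | None = None) -> logging.Logger:
    return logging.getLogger(f"{_LOGGER_NAME}.{name}" if name else _LOGGER_NAME)


def setup_logging(level: int = logging.INFO) -> None:
    """Route package logs to standard error with a compact format."""
    logger = logging.getLogger(_LOGGER_NAME)
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(
            logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        logger.addHandler(handler)
    logger.setLevel(level)


# Named sub-streams: every random procedure derives its generator from the
# master seed plus a fixed stream tag, so adding a new draw never perturbs
# existing ones.
STREAMS = {
    "proportions": 1,
    "metabolites": 2,
    "expression": 3,
    "metadata": 4,
    "planting": 5,
    "pathways": 6,
    "cells": 7,
    "density_perm": 8,
    "rf_splits": 9,
    "rf_model": 10,
    "severity": 11,
}


def child_seed(master_seed: int, stream: str, index: int = 0) -> int:
    """A derived 31-bit seed for a named sub-stream of the master seed."""
    ss = np.random.SeedSequence(
        int(master_seed) % (2**31), spawn_key=(STREAMS[stream], int(index)))
    return int(ss.generate_state(1)[0] % (2**31))


def child_rng(master_seed: int, stream: str, index: int = 0) -> np.random.Generator:
    ss = np.random.SeedSequence(
        int(master_seed) % (2**31), spawn_key=(STREAMS[stream], int(index)))
    return np.random.default_rng(ss)
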