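"""Shared fixtures: random loop-free pedigrees with random observations."""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
import pytest

from digenic.likelihood import _obs_indicator
from digenic.pedigree import (
    Affection,
    Individual,
    Pedigree,
    Sex,
    TObs,
    XInactivation,
    XObs,
)
from digenic.simulate import StructureTemplate, make_structure

_AFFS = [Affection.UNKNOWN, Affection.AFFECTED, Affection.UNAFFECTED]
_TOBS = [TObs.UNKNOWN, TObs.HOM_WT, TObs.HET_MUT]


def random_pedigree(
    rng: np.random.Generator,
    max_members: int = 8,
    max_configs: int = 500_000,
    family_id: str = "R",
) -> Pedigree:
    """Random loop-free pedigree with random two-locus observations.

    Pedigrees whose observation-consistent genotype space exceeds
    ``max_configs`` are resampled so the brute-force oracle stays cheap.
    """
    template = StructureTemplate(
        p_three_generations=0.5, sibship=(1, 3), p_marry=0.5, sibship_g3=(1, 2)
    )
    while True:
        ped = make_structure(template, rng, family_id)
        if len(ped) > max_members:
            continue
        members = []
        for m in ped.members:
            aff = _AFFS[rng.choice(3, p=[0.3, 0.35, 0.35])]
            if m.sex is Sex.MALE:
                s = [XObs.UNKNOWN, XObs.WT, XObs.HEMI_MUT][rng.choice(3, p=[0.3, 0.35, 0.35])]
                xi = XInactivation.UNKNOWN
            else:
                s = [XObs.UNKNOWN, XObs.WT, XObs.HET_CARRIER][rng.choice(3, p=[0.3, 0.35, 0.35])]
                xi = list(XInactivation)[rng.choice(4)]
            t = _TOBS[rng.choice(3, p=[0.3, 0.35, 0.35])]
            members.append(replace(m, affection=aff, s_obs=s, t_obs=t, xi_status=xi))
        ped = Pedigree(family_id, members)
        n_cfg = math.prod(int((_obs_indicator(m) > 0).sum()) for m in ped.members)
        if n_cfg <= max_configs:
            return ped


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240301)


def make_trio(
    child_sex: Sex = Sex.MALE,
    child_affection: Affection = Affection.UNKNOWN,
    **child_kwargs,
) -> Pedigree:
    return Pedigree(
        "TRIO",
        [
            Individual(id="fa", sex=Sex.MALE),
            Individual(id="mo", sex=Sex.FEMALE),
            Individual(
                id="kid",
                father_id="fa",
                mother_id="mo",
                sex=child_sex,
                affection=child_affection,
                **child_kwargs,
            ),
        ],
    )
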