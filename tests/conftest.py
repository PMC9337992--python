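"""Shared fixtures: the toy CDS locus and chromosome-mirroring helpers used
by the ORF and strand-symmetry tests (re-exported from the generator
module so acceptance scripts can build the same constructions)."""

from __future__ import annotations

import pytest

from vmtools.synth import STOP_FREE_CODONS, gen_cds_locus, mirror_genome

SAFE_CODONS = STOP_FREE_CODONS


def build_toy_locus(intron1_codons=None, exon2_codons=None, seed: int = 0):
    return gen_cds_locus(seed=seed, intron1_codons=intron1_codons,
                         exon2_codons=exon2_codons)


mirror_locus = mirror_genome


@pytest.fixture
def toy_locus():
    return build_toy_locus()
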