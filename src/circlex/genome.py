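"""Chromosome inventory used by the simulator and the positional scans.

Lengths are hg19-scale constants; the statistics downstream depend only on
their order of magnitude, not on the exact assembly.
"""

from __future__ import annotations

AUTOSOMES: tuple[str, ...] = tuple(f"chr{i}" for i in range(1, 23))
CHRX = "chrX"
CHROMOSOMES: tuple[str, ...] = AUTOSOMES + (CHRX,)

CHROM_LENGTHS: dict[str, int] = {
    "chr1": 249_250_621,
    "chr2": 243_199_373,
    "chr3": 198_022_430,
    "chr4": 191_154_276,
    "chr5": 180_915_260,
    "chr6": 171_115_067,
    "chr7": 159_138_663,
    "chr8": 146_364_022,
    "chr9": 141_213_431,
    "chr10": 135_534_747,
    "chr11": 135_006_516,
    "chr12": 133_851_895,
    "chr13": 115_169_878,
    "chr14": 107_349_540,
    "chr15": 102_531_392,
    "chr16": 90_354_753,
    "chr17": 81_195_210,
    "chr18": 78_077_248,
    "chr19": 59_128_983,
    "chr20": 63_025_520,
    "chr21": 48_129_895,
    "chr22": 51_304_566,
    CHRX: 155_270_560,
}
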