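"""Reference genome metadata for Bos taurus (ARS-UCD1.2 autosomes)."""

from __future__ import annotations

#: ARS-UCD1.2 autosome lengths in bp (BTA1..BTA29).
ARS_UCD12_AUTOSOME_LENGTHS: dict[str, int] = {
    "1": 158_534_110,
    "2": 136_231_102,
    "3": 121_005_158,
    "4": 120_000_601,
    "5": 120_089_316,
    "6": 117_806_340,
    "7": 110_682_743,
    "8": 113_319_770,
    "9": 105_454_467,
    "10": 103_308_737,
    "11": 106_982_474,
    "12": 87_216_183,
    "13": 83_472_345,
    "14": 82_403_003,
    "15": 85_007_780,
    "16": 81_013_979,
    "17": 73_167_244,
    "18": 65_820_629,
    "19": 63_449_741,
    "20": 71_974_595,
    "21": 69_862_954,
    "22": 60_773_035,
    "23": 52_498_615,
    "24": 62_317_253,
    "25": 42_350_435,
    "26": 51_992_305,
    "27": 45_612_108,
    "28": 45_940_150,
    "29": 51_098_607,
}

#: Chromosome labels accepted as cattle autosomes.
AUTOSOMES: frozenset[str] = frozenset(str(i) for i in range(1, 30))


def normalize_chromosome(label: str) -> str:
    """Strip ``chr``/``BTA`` prefixes and return the bare chromosome label."""
    s = str(label).strip()
    for prefix in ("chr", "Chr", "CHR", "BTA", "bta"):
        if s.startswith(prefix):
            s = s[len(prefix):]
            break
    return s


def chromosome_sort_key(label: str):
    """Numeric-first sort key so '2' < '10' < 'X'."""
    s = normalize_chromosome(label)
    return (0, int(s)) if s.isdigit() else (1, s)
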