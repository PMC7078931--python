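"""Species roster for simulated multispecies auditory surveys.

The default roster is the ten prairie songbird species of the study system:
grassland/sagebrush-associated birds of central Montana, identified by their
standard 4-letter alpha codes.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class SpeciesEntry:
    code: str
    common_name: str
    scientific_name: str


@dataclass(frozen=True)
class SpeciesRoster:
    """An ordered set of species with unique 4-letter alpha codes."""

    entries: tuple[SpeciesEntry, ...]

    def __post_init__(self) -> None:
        codes = [e.code for e in self.entries]
        if len(set(codes)) != len(codes):
            raise ValueError("species codes must be unique")
        for c in codes:
            if len(c) != 4 or not c.isalpha():
                raise ValueError(f"invalid 4-letter alpha code: {c!r}")

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(e.code for e in self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, code: str) -> bool:
        return code in self.codes

    def index(self, code: str) -> int:
        return self.codes.index(code)


DEFAULT_ROSTER = SpeciesRoster(
    entries=(
        SpeciesEntry("BHCO", "Brown-headed Cowbird", "Molothrus ater"),
        SpeciesEntry("BRSP", "Brewer's Sparrow", "Spizella breweri"),
        SpeciesEntry("HOLA", "Horned Lark", "Eremophila alpestris"),
        SpeciesEntry("KILL", "Killdeer", "Charadrius vociferous"),
        SpeciesEntry("LARB", "Lark Bunting", "Calamospiza melanocorys"),
        SpeciesEntry("LBCU", "Long-billed Curlew", "Numenius americanus"),
        SpeciesEntry("MCLO", "McCown's Longspur", "Rhynchophanes mccownii"),
        SpeciesEntry("SAVS", "Savannah Sparrow", "Passerculus sandwichensis"),
        SpeciesEntry("VESP", "Vesper Sparrow", "Pooectes graminius"),
        SpeciesEntry("WEME", "Western Meadowlark", "Sturnella neglecta"),
    )
)

# Similar-sounding pairs known to drive asymmetric misidentification.
SIMILAR_PAIRS = (("MCLO", "HOLA"), ("KILL", "LBCU"))
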