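"""Desikan-region to 10-20 electrode association table.

The table follows Giacometti's mapping of Desikan cortical parcels onto
overlying 10-20 electrodes and is shipped verbatim as a CSV resource,
including a few nonstandard labels (N1, N2, F9, F10) kept for fidelity to the
published association. Matching against recording montages is
case-insensitive.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

__all__ = ["RegionMap", "load_region_map", "electrodes_for", "validate_against"]


@dataclass(frozen=True)
class RegionCoverage:
    """Per-region montage coverage report."""

    region: str
    electrodes: tuple[str, ...]
    missing: tuple[str, ...]

    @property
    def usable(self) -> bool:
        return not self.missing


class RegionMap:
    """Ordered mapping of cortical region name -> tuple of electrode labels."""

    def __init__(self, regions: dict[str, tuple[str, ...]]):
        if len(set(regions)) != len(regions):
            raise ValueError("region names must be unique")
        for name, elecs in regions.items():
            if not elecs:
                raise ValueError(f"region {name!r} has an empty electrode list")
        self._regions = {name: tuple(elecs) for name, elecs in regions.items()}

    def __iter__(self):
        return iter(self._regions)

    def __len__(self) -> int:
        return len(self._regions)

    def __contains__(self, region: str) -> bool:
        return region in self._regions

    def items(self):
        return self._regions.items()

    def electrodes_for(self, region: str) -> list[str]:
        """Return the electrode labels associated with ``region``, verbatim."""
        try:
            return list(self._regions[region])
        except KeyError:
            valid = ", ".join(sorted(self._regions))
            raise KeyError(
                f"unknown region {region!r}; valid regions: {valid}"
            ) from None

    def validate_against(self, channel_names: list[str]) -> list[RegionCoverage]:
        """Report, per region, which electrodes are absent from a montage.

        Matching is case-insensitive. Regions with no missing electrode are
        flagged usable.
        """
        have = {name.lower() for name in channel_names}
        report = []
        for region, elecs in self._regions.items():
            missing = tuple(e for e in elecs if e.lower() not in have)
            report.append(RegionCoverage(region, elecs, missing))
        return report

    def usable_regions(self, channel_names: list[str]) -> list[str]:
        return [c.region for c in self.validate_against(channel_names) if c.usable]


def load_region_map() -> RegionMap:
    """Load the packaged Desikan-region / 10-20 electrode association table."""
    text = (
        resources.files("eegdep.resources").joinpath("desikan_1020.csv").read_text()
    )
    lines = [ln for ln in text.splitlines() if ln.strip()]
    regions: dict[str, tuple[str, ...]] = {}
    for line in lines[1:]:  # skip header
        region, elecs = line.split(",", 1)
        regions[region] = tuple(elecs.split(";"))
    return RegionMap(regions)


def electrodes_for(region: str) -> list[str]:
    """Module-level convenience over the packaged table."""
    return load_region_map().electrodes_for(region)


def validate_against(recording) -> list[RegionCoverage]:
    """Coverage report of the packaged table against a recording's montage."""
    return load_region_map().validate_against(recording.channel_names)
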