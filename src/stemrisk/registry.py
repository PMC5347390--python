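"""Built-in cancer-site division counts and named presets.

``n1``/``n2`` are the symmetric and asymmetric stem-cell division counts
per site used by the exact recurrence and the multistage model.
"""

from __future__ import annotations

from dataclasses import dataclass
from types import MappingProxyType

__all__ = ["SiteParams", "SITE_REGISTRY", "load_site_registry", "get_site", "FRANK_DEFAULT"]


@dataclass(frozen=True)
class SiteParams:
    """A cancer site's stem-cell division counts."""

    site: str
    n1: int
    n2: int


_SITES = (
    SiteParams("acute myeloid leukemia", 27, 960),
    SiteParams("basal cell carcinoma", 32, 608),
    SiteParams("colorectal adenocarcinoma", 28, 5840),
    SiteParams("esophageal squamous cell carcinoma", 20, 1390),
    SiteParams("lung adenocarcinoma", 30, 6),
    SiteParams("osteosarcoma", 22, 5),
    SiteParams("thyroid papillary/follicular carcinoma", 26, 7),
)

#: immutable mapping site name -> SiteParams
SITE_REGISTRY = MappingProxyType({s.site: s for s in _SITES})

#: tissue-simulator preset: 1024 asymmetric stem divisions, 10 symmetric
#: transit divisions, i.e. 2**20 cells in the completed tissue
FRANK_DEFAULT = {"n1": 1024, "n2": 10}


def load_site_registry():
    """The embedded site registry (read-only mapping)."""
    return SITE_REGISTRY


def get_site(name: str) -> SiteParams:
    """Case-insensitive site lookup; raises KeyError for unknown names."""
    key = name.strip().lower()
    try:
        return SITE_REGISTRY[key]
    except KeyError:
        known = ", ".join(sorted(SITE_REGISTRY))
        raise KeyError(f"unknown cancer site {name!r}; known sites: {known}") from None
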