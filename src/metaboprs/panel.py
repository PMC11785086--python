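"""Metabolite panel registry.

The NMR metabolomics platform quantifies a fixed panel of absolute metabolite
concentrations; a subset of the panel is certified for diagnostic use and is
analysed separately in the prediction models. The panel object keeps the
ordered metabolite names together with the certified flags so every stage of
the pipeline agrees on column identity and order.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class MetabolitePanel:
    """Ordered metabolite name registry with certified-subset flags.

    Parameters
    ----------
    names
        Unique metabolite identifiers, in fixed column order.
    certified
        One flag per name; ``True`` marks membership in the certified
        (diagnostic-grade) subset.
    """

    names: tuple[str, ...]
    certified: tuple[bool, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.names:
            raise ValueError("panel must contain at least one metabolite")
        if len(set(self.names)) != len(self.names):
            raise ValueError("metabolite names must be unique")
        cert = self.certified if self.certified else tuple(False for _ in self.names)
        if len(cert) != len(self.names):
            raise ValueError("certified flags must match the number of names")
        object.__setattr__(self, "certified", tuple(bool(c) for c in cert))

    @property
    def size(self) -> int:
        return len(self.names)

    @property
    def certified_names(self) -> tuple[str, ...]:
        return tuple(n for n, c in zip(self.names, self.certified) if c)

    def subset_names(self, which: str) -> tuple[str, ...]:
        """Return metabolite names for a named panel subset.

        ``which`` is one of ``"none"``, ``"certified27"`` or ``"full168"``
        (the latter two are conventional labels; they resolve to the certified
        subset and the full panel of whatever size this registry holds).
        """
        if which == "none":
            return ()
        if which == "certified27":
            return self.certified_names
        if which == "full168":
            return self.names
        raise ValueError(f"unknown metabolite set {which!r}")


#: Resilience trio reported for high-genetic-risk strata: glycolysis end
#: products plus the TCA-cycle entry metabolite.
RESILIENCE_TRIO = ("lactate", "pyruvate", "citrate")


def default_panel(n_metabolites: int = 168, n_certified: int = 27) -> MetabolitePanel:
    """Synthetic stand-in for the 168-metabolite NMR panel.

    The first three names are the glycolysis/TCA metabolites used as the
    default resilience set; the remainder are generic placeholders. The
    first ``n_certified`` names are flagged as the certified subset.
    """
    if n_metabolites < 1:
        raise ValueError("n_metabolites must be positive")
    n_certified = min(n_certified, n_metabolites)
    base = list(RESILIENCE_TRIO[:n_metabolites])
    base += [f"met_{i:03d}" for i in range(len(base) + 1, n_metabolites + 1)]
    certified = tuple(i < n_certified for i in range(n_metabolites))
    return MetabolitePanel(names=tuple(base), certified=certified)
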