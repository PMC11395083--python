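"""Atomic de-excitation: fluorescence and Auger-cascade surrogate.

Each element carries one effective level per major shell (K, L, M, N for
gold).  A vacancy either emits a characteristic photon of energy
B_i - B_next (probability = shell fluorescence yield; the vacancy moves one
shell outward) or an Auger electron of energy B_i - 2*B_next, leaving two
vacancies in the next shell.  The cascade recurses until shell binding
drops below 100 eV, where the residual is released as a local electron.
Emitted energies always sum exactly to the initial vacancy's binding
energy, so energy is conserved by construction.  Multi-electron
correlation effects of real Auger cascades are not modeled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

__all__ = ["RelaxationModel", "emit_relaxation", "get_relaxation_model"]

_LOCAL_EV = 100.0


@dataclass(frozen=True)
class EmittedQuantum:
    kind: str  # "photon" | "electron"
    energy_eV: float


class RelaxationModel:
    def __init__(self, element: str, doc: dict):
        self.element = element
        self.shells: list[str] = doc["shells"]
        self.binding_eV: dict[str, float] = doc["binding_eV"]
        self.fluorescence_yield: dict[str, float] = doc["fluorescence_yield"]
        self.photo_fractions: dict[str, dict[str, float]] = doc[
            "photoionization_fractions"]

    def select_shell(self, photon_energy_eV: float, rng) -> str:
        """Pick the ionized shell for a photoabsorption at this energy."""
        order = self.shells
        accessible = [s for s in order if self.binding_eV[s] <= photon_energy_eV]
        if not accessible:
            raise ValueError(
                f"photon energy {photon_energy_eV} eV below all {self.element} shells")
        top = accessible[0]
        key = f"above_{top}"
        fractions = self.photo_fractions.get(key)
        if fractions is None:
            # innermost accessible shell has no dedicated row (e.g. only the
            # outermost shell is reachable)
            fractions = self.photo_fractions.get(f"below_{order[-2]}",
                                                 {top: 1.0})
        # restrict to accessible shells and renormalize
        items = [(s, f) for s, f in fractions.items() if s in accessible]
        total = sum(f for _, f in items)
        u = rng.random() * total
        acc = 0.0
        for s, f in items:
            acc += f
            if u <= acc:
                return s
        return items[-1][0]

    def _next_shell(self, shell: str) -> str | None:
        i = self.shells.index(shell)
        return self.shells[i + 1] if i + 1 < len(self.shells) else None

    def relax(self, shell: str, rng) -> list[EmittedQuantum]:
        """Full cascade from one vacancy; energies sum to the binding energy."""
        out: list[EmittedQuantum] = []
        stack = [shell]
        while stack:
            s = stack.pop()
            b = self.binding_eV[s]
            nxt = self._next_shell(s)
            if nxt is None or b < _LOCAL_EV:
                # outermost level: release binding as a local soft electron
                out.append(EmittedQuantum("electron", b))
                continue
            b_next = self.binding_eV[nxt]
            if rng.random() < self.fluorescence_yield[s]:
                out.append(EmittedQuantum("photon", b - b_next))
                stack.append(nxt)
            else:
                auger = b - 2.0 * b_next
                if auger <= 0:
                    # shell spacing forbids Auger; release as one electron
                    out.append(EmittedQuantum("electron", b))
                    continue
                out.append(EmittedQuantum("electron", auger))
                stack.append(nxt)
                stack.append(nxt)
        return out


def _load() -> dict[str, RelaxationModel]:
    text = (resources.files("nanodose.data")
            .joinpath("atomic_relaxation.json").read_text())
    doc = json.loads(text)
    return {sym: RelaxationModel(sym, spec) for sym, spec in doc.items()
            if sym != "comment"}


_MODELS = _load()


def get_relaxation_model(element: str) -> RelaxationModel:
    try:
        return _MODELS[element]
    except KeyError:
        raise KeyError(f"no relaxation data for element {element!r}") from None


def emit_relaxation(vacancy_shell: str, element: str, rng) -> list[EmittedQuantum]:
    """Relax a vacancy; returns the emitted photons/electrons.

    Raises for unsupported elements or shells.
    """
    model = get_relaxation_model(element)
    if vacancy_shell not in model.shells:
        raise ValueError(
            f"element {element} has no shell {vacancy_shell!r} in the model")
    return model.relax(vacancy_shell, rng)
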