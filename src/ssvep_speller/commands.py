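"""Control-command alphabet and its fixed mapping to stimulation frequencies.

The speller is driven by five flicker frequencies, each an integer division
of the 60 Hz display refresh.  The frequency -> command assignment is a fixed
bijection: 6.67 Hz -> UP, 7.5 Hz -> RIGHT, 8.57 Hz -> DOWN, 10 Hz -> LEFT,
12 Hz -> SELECT.  ``NONE`` denotes "no command" (rest / no emission).
"""

from __future__ import annotations

import enum


class Command(str, enum.Enum):
    UP = "UP"
    RIGHT = "RIGHT"
    DOWN = "DOWN"
    LEFT = "LEFT"
    SELECT = "SELECT"
    NONE = "NONE"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Nominal stimulation frequencies in Hz, in fixed command order.
STIMULUS_FREQUENCIES_HZ: tuple[float, ...] = (6.67, 7.5, 8.57, 10.0, 12.0)

#: Fixed bijection nominal frequency -> command.
FREQUENCY_TO_COMMAND: dict[float, Command] = {
    6.67: Command.UP,
    7.5: Command.RIGHT,
    8.57: Command.DOWN,
    10.0: Command.LEFT,
    12.0: Command.SELECT,
}

COMMAND_TO_FREQUENCY: dict[Command, float] = {
    c: f for f, c in FREQUENCY_TO_COMMAND.items()
}

#: The five active commands (NONE excluded), in frequency order.
ACTIVE_COMMANDS: tuple[Command, ...] = tuple(FREQUENCY_TO_COMMAND.values())


def map_frequency_to_command(f_hz: float, tol_hz: float = 0.05) -> Command:
    """Map a stimulation frequency to its control command.

    Frequencies are matched within ``tol_hz`` so that realized frame-locked
    values (e.g. 60/7 = 8.5714 Hz) resolve to their nominal slot (8.57 Hz).
    """
    for nominal, cmd in FREQUENCY_TO_COMMAND.items():
        if abs(f_hz - nominal) <= tol_hz:
            return cmd
    raise ValueError(f"frequency {f_hz} Hz is not in the stimulus set")


def map_command_to_frequency(command: Command) -> float:
    """Inverse of :func:`map_frequency_to_command` (nominal Hz)."""
    if command not in COMMAND_TO_FREQUENCY:
        raise ValueError(f"{command} has no stimulation frequency")
    return COMMAND_TO_FREQUENCY[command]
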