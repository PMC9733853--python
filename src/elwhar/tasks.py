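"""The ten-task vocabulary for electrical line worker activity recognition.

Six timed tasks (3 minutes each) and four repetition-counted tasks, performed
in a fixed session order: general mobility first, then general work tasks,
then specialized work tasks.
"""

# Canonical label set, alphabetical.
TASKS: tuple[str, ...] = (
    "electrical_panel",
    "hoisting",
    "ladder",
    "lifting",
    "overhead",
    "pushing",
    "sitting",
    "standing",
    "typing",
    "walking",
)

# Session order: mobility block, work-task block, specialized block.
SESSION_ORDER: tuple[str, ...] = (
    "sitting",
    "standing",
    "walking",
    "hoisting",
    "lifting",
    "pushing",
    "ladder",
    "typing",
    "electrical_panel",
    "overhead",
)

AXES: tuple[str, str, str] = ("x", "y", "z")
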