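"""Standard module color sequence (size-ordered; grey = unassigned)."""

GREY = "grey"

# Conventional ordering used by co-expression tooling: the largest module
# is turquoise, the second blue, and so on.  Beyond the list, modules are
# named module_<rank>.
STANDARD_COLORS = (
    "turquoise",
    "blue",
    "brown",
    "yellow",
    "green",
    "red",
    "black",
    "pink",
    "magenta",
    "purple",
    "greenyellow",
    "tan",
    "salmon",
    "cyan",
    "midnightblue",
    "lightcyan",
    "grey60",
    "lightgreen",
    "lightyellow",
    "royalblue",
    "darkred",
    "darkgreen",
    "darkturquoise",
    "darkgrey",
    "orange",
    "darkorange",
    "white",
    "skyblue",
    "saddlebrown",
    "steelblue",
    "paleturquoise",
    "violet",
    "darkolivegreen",
    "darkmagenta",
    "sienna3",
    "yellowgreen",
    "skyblue3",
    "plum1",
    "orangered4",
    "mediumpurple3",
    "lightsteelblue1",
    "lightcyan1",
    "ivory",
    "floralwhite",
    "darkorange2",
    "brown4",
    "bisque4",
    "darkslateblue",
    "plum2",
    "thistle2",
)


def color_for_rank(rank: int) -> str:
    """Color for a size-rank (0-based); overflow ranks get module_<n>."""
    if rank < len(STANDARD_COLORS):
        return STANDARD_COLORS[rank]
    return f"module_{rank + 1}"
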