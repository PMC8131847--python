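"""Fixed module color palette.

Modules are named by decreasing size from this ordered list of 180 distinct
color names, so labels are deterministic across runs: the largest module is
always "turquoise", the unassigned bucket is always "grey".
"""

MODULE_COLORS: tuple[str, ...] = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "lightgreen", "lightyellow", "royalblue",
    "darkred", "darkgreen", "darkturquoise", "darkgrey", "orange",
    "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta", "mediumorchid",
    "darkseagreen", "yellowgreen", "plum", "orangered", "mediumpurple",
    "lightsteelblue", "ivory", "floralwhite", "darkslateblue", "thistle",
    "maroon", "lavenderblush", "honeydew", "coral", "antiquewhite",
    "navajowhite", "mediumorchid4", "brown4", "bisque", "sienna",
    "palevioletred", "lightpink", "darkseagreen4",
    "yellow4", "chocolate", "firebrick", "gold",
    "khaki", "olive", "peru", "rosybrown", "seagreen", "slateblue",
    "tomato", "wheat", "aquamarine", "azure", "beige", "blueviolet",
    "burlywood", "cadetblue", "chartreuse", "cornflowerblue", "crimson",
    "darkblue", "darkcyan", "darkgoldenrod", "darkkhaki", "darkorchid",
    "darksalmon", "darkslategrey", "darkviolet", "deeppink", "deepskyblue",
    "dodgerblue", "forestgreen", "fuchsia", "gainsboro", "goldenrod",
    "hotpink", "indianred", "indigo", "lavender", "lawngreen",
    "lemonchiffon", "lightblue", "lightcoral", "lightgoldenrod",
    "lightsalmon", "lightseagreen", "lightskyblue", "lightslategrey",
    "limegreen", "linen", "mediumaquamarine", "mediumblue",
    "mediumseagreen", "mediumslateblue", "mediumspringgreen",
    "mediumturquoise", "mediumvioletred", "mintcream", "mistyrose",
    "moccasin", "navy", "oldlace", "olivedrab", "orchid", "palegoldenrod",
    "palegreen", "papayawhip", "peachpuff", "powderblue", "rebeccapurple",
    "sandybrown", "seashell", "sienna3", "silver", "slategrey", "snow",
    "springgreen", "teal", "thistle4", "turquoise4", "violetred",
    "aliceblue", "blanchedalmond",
    "chartreuse4", "chocolate4", "coral4", "cornsilk", "cyan4",
    "darkgoldenrod4", "darkolivegreen4", "darkorange2", "darkorchid4",
    "deeppink4", "dodgerblue4", "firebrick4", "gold4", "goldenrod4",
    "green4", "honeydew4", "hotpink4", "indianred4", "khaki4",
    "lightblue4", "lightcyan4", "lightpink4", "lightsalmon4", "magenta4",
    "maroon4", "mediumpurple4", "mistyrose4", "navajowhite4", "olivedrab4",
    "orange4", "orchid4", "palegreen4", "peachpuff4", "pink4", "plum4",
    "purple4", "red4", "royalblue4", "salmon4",
)

GREY = "grey"

assert len(MODULE_COLORS) == 180
assert len(set(MODULE_COLORS)) == 180
assert GREY not in MODULE_COLORS
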