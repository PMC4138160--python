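"""Build the packaged cohort fixture JSONs from the published group statistics."""
import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
from gaitsep.variables import VARIABLE_NAMES, SIDES, TIMEPOINTS

# Printed general-group values: (joint, plane, timepoint) ->
#   {side: {gender: (mean, sd)}}
GENERAL_PRINTED = {
    ("hip", "frontal", "maxpeak"): {
        "L": {"male": (9.50, 4.30), "female": (11.45, 4.03)},
        "R": {"male": (8.00, 3.62), "female": (10.63, 3.74)},
    },
    ("hip", "frontal", "minpeak"): {
        "L": {"male": (-0.15, 3.49), "female": (1.20, 3.79)},
        "R": {"male": (-0.91, 3.70), "female": (-0.14, 3.89)},
    },
    ("hip", "frontal", "toeoff"): {
        "L": {"male": (3.06, 3.35), "female": (5.97, 3.06)},
        "R": {"male": (4.05, 3.14), "female": (6.72, 3.36)},
    },
    ("hip", "transverse", "touchdown"): {
        "L": {"male": (8.87, 12.03), "female": (12.87, 6.90)},
        "R": {"male": (11.75, 6.57), "female": (14.85, 6.43)},
    },
    ("hip", "transverse", "maxpeak"): {
        "L": {"male": (10.34, 11.99), "female": (14.15, 6.86)},
        "R": {"male": (13.32, 6.31), "female": (16.49, 6.26)},
    },
    ("knee", "frontal", "touchdown"): {
        "L": {"male": (-5.59, 3.72), "female": (-8.01, 3.41)},
        "R": {"male": (-6.31, 3.53), "female": (-8.59, 3.49)},
    },
    ("knee", "frontal", "maxpeak"): {
        "L": {"male": (-8.55, 5.18), "female": (-10.75, 4.35)},
        "R": {"male": (-9.94, 4.79), "female": (-11.95, 4.50)},
    },
    ("knee", "frontal", "minpeak"): {
        "L": {"male": (-2.99, 4.67), "female": (-5.46, 3.89)},
        "R": {"male": (-4.33, 4.05), "female": (-6.61, 3.78)},
    },
    ("knee", "frontal", "toeoff"): {
        "L": {"male": (-5.31, 3.95), "female": (-7.70, 3.37)},
        "R": {"male": (-6.11, 3.59), "female": (-8.67, 3.39)},
    },
    ("knee", "sagittal", "minpeak"): {
        "L": {"male": (14.88, 5.43), "female": (12.66, 5.45)},
        "R": {"male": (13.26, 4.78), "female": (12.02, 5.02)},
    },
    ("knee", "sagittal", "toeoff"): {
        "L": {"male": (17.28, 6.31), "female": (14.25, 6.37)},
        "R": {"male": (15.60, 5.69), "female": (13.49, 5.76)},
    },
    ("ankle", "frontal", "minpeak"): {
        "L": {"male": (-7.30, 3.18), "female": (-5.54, 3.13)},
        "R": {"male": (-7.13, 3.07), "female": (-5.64, 3.16)},
    },
    ("ankle", "sagittal", "minpeak"): {
        "L": {"male": (-23.37, 2.72), "female": (-22.50, 2.73)},
        "R": {"male": (-22.92, 2.81), "female": (-21.99, 2.93)},
    },
}

YOUNG_PRINTED = {
    ("hip", "frontal", "toeoff"): {
        "L": {"male": (0.69, 2.70), "female": (5.25, 2.47)},
        "R": {"male": (2.80, 3.13), "female": (6.46, 2.90)},
    },
    ("hip", "transverse", "touchdown"): {
        "L": {"male": (7.10, 7.56), "female": (14.86, 5.95)},
        "R": {"male": (12.82, 7.41), "female": (14.89, 6.59)},
    },
    ("hip", "transverse", "maxpeak"): {
        "L": {"male": (8.32, 7.98), "female": (16.32, 6.17)},
        "R": {"male": (14.08, 7.35), "female": (17.28, 6.36)},
    },
    ("hip", "transverse", "minpeak"): {
        "L": {"male": (-8.26, 6.05), "female": (-1.29, 5.94)},
        "R": {"male": (-1.89, 5.90), "female": (-0.03, 7.81)},
    },
    ("hip", "transverse", "toeoff"): {
        "L": {"male": (-7.94, 5.93), "female": (-1.27, 5.95)},
        "R": {"male": (-1.51, 5.87), "female": (-0.02, 7.81)},
    },
    ("knee", "sagittal", "touchdown"): {
        "L": {"male": (18.19, 2.99), "female": (14.86, 4.97)},
        "R": {"male": (17.24, 3.46), "female": (12.96, 5.13)},
    },
    ("knee", "sagittal", "maxpeak"): {
        "L": {"male": (48.19, 5.61), "female": (42.50, 6.20)},
        "R": {"male": (46.45, 5.05), "female": (41.27, 6.27)},
    },
    ("knee", "sagittal", "minpeak"): {
        "L": {"male": (15.65, 4.09), "female": (11.91, 5.22)},
        "R": {"male": (14.83, 4.03), "female": (10.58, 4.48)},
    },
    ("knee", "sagittal", "toeoff"): {
        "L": {"male": (17.81, 5.54), "female": (13.21, 6.27)},
        "R": {"male": (17.11, 4.75), "female": (12.06, 4.79)},
    },
    ("ankle", "sagittal", "minpeak"): {
        "L": {"male": (-24.65, 2.55), "female": (-22.25, 2.42)},
        "R": {"male": (-24.00, 1.98), "female": (-21.24, 2.82)},
    },
}

OLDER_PRINTED = {
    ("hip", "frontal", "toeoff"): {
        "L": {"male": (4.77, 3.48), "female": (8.40, 2.88)},
        "R": {"male": (4.80, 2.98), "female": (7.55, 3.08)},
    },
    ("knee", "frontal", "touchdown"): {
        "L": {"male": (-5.51, 3.27), "female": (-9.12, 3.59)},
        "R": {"male": (-6.46, 3.61), "female": (-9.40, 2.79)},
    },
    ("knee", "frontal", "maxpeak"): {
        "L": {"male": (-7.68, 4.36), "female": (-11.82, 5.02)},
        "R": {"male": (-9.17, 4.52), "female": (-11.81, 4.74)},
    },
    ("knee", "frontal", "minpeak"): {
        "L": {"male": (-2.78, 4.92), "female": (-7.10, 4.36)},
        "R": {"male": (-4.28, 4.63), "female": (-6.81, 4.48)},
    },
    ("knee", "frontal", "toeoff"): {
        "L": {"male": (-5.99, 3.81), "female": (-9.30, 4.01)},
        "R": {"male": (-6.43, 4.29), "female": (-8.73, 3.23)},
    },
    ("ankle", "frontal", "minpeak"): {
        "L": {"male": (-7.30, 2.62), "female": (-4.99, 2.75)},
        "R": {"male": (-7.14, 3.52), "female": (-4.74, 3.32)},
    },
}

# Gender-neutral defaults (same both sides, both genders) for variables the
# published comparison tables do not print. Values are typical recreational
# treadmill-running stance kinematics in the same sign conventions as the
# printed rows (knee abduction negative, ankle eversion negative, peak
# dorsiflexion negative).
DEFAULTS = {
    ("hip", "sagittal", "touchdown"): (32.0, 5.0),
    ("hip", "sagittal", "maxpeak"): (34.0, 5.0),
    ("hip", "sagittal", "minpeak"): (-8.0, 5.0),
    ("hip", "sagittal", "toeoff"): (-6.0, 5.0),
    ("hip", "frontal", "touchdown"): (6.0, 3.5),
    ("hip", "transverse", "minpeak"): (-3.0, 7.0),
    ("hip", "transverse", "toeoff"): (-2.0, 7.0),
    ("knee", "sagittal", "touchdown"): (16.0, 4.0),
    ("knee", "sagittal", "maxpeak"): (45.0, 6.0),
    ("knee", "transverse", "touchdown"): (-2.0, 4.0),
    ("knee", "transverse", "maxpeak"): (8.0, 5.0),
    ("knee", "transverse", "minpeak"): (-6.0, 4.0),
    ("knee", "transverse", "toeoff"): (0.0, 5.0),
    ("ankle", "sagittal", "touchdown"): (-5.0, 4.0),
    ("ankle", "sagittal", "maxpeak"): (15.0, 6.0),
    ("ankle", "sagittal", "toeoff"): (12.0, 6.0),
    ("ankle", "frontal", "touchdown"): (2.0, 3.0),
    ("ankle", "frontal", "maxpeak"): (5.0, 3.0),
    ("ankle", "frontal", "toeoff"): (3.0, 4.0),
    ("ankle", "transverse", "touchdown"): (-2.0, 4.0),
    ("ankle", "transverse", "maxpeak"): (4.0, 4.0),
    ("ankle", "transverse", "minpeak"): (-8.0, 4.0),
    ("ankle", "transverse", "toeoff"): (-1.0, 4.0),
}


def build_variables(printed, inherit=None):
    """Map each of the 72 names to {male: [mean, sd], female: [...], source}."""
    out = {}
    for name in VARIABLE_NAMES:
        side, joint, plane, tp = name.split("_")
        key = (joint, plane, tp)
        if key in printed:
            cell = printed[key][side]
            out[name] = {
                "male": list(cell["male"]),
                "female": list(cell["female"]),
                "source": "printed",
            }
        elif inherit is not None:
            cell = dict(inherit[name])
            cell["source"] = (
                "inherited_general" if cell["source"] == "printed" else "default"
            )
            out[name] = cell
        else:
            mean, sd = DEFAULTS[key]
            out[name] = {
                "male": [mean, sd],
                "female": [mean, sd],
                "source": "default",
            }
    return out


general_vars = build_variables(GENERAL_PRINTED)

fixtures = {
    "general": {
        "name": "general",
        "description": (
            "General running cohort (ages 18-72). Printed per-gender per-side "
            "means/SDs for 26 variables; remaining 46 use gender-neutral "
            "defaults. Ages drawn from a three-stratum mixture so the young "
            "(18-26) and elderly (55-72) closed bands contain exactly the "
            "published subgroup counts."
        ),
        "groups": {
            "male": {
                "n": 220,
                "age_strata": [[16, 18.0, 26.0], [170, 26.5, 54.5], [34, 55.0, 72.0]],
            },
            "female": {
                "n": 263,
                "age_strata": [[40, 18.0, 26.0], [206, 26.5, 54.5], [17, 55.0, 72.0]],
            },
        },
        "variables": general_vars,
    },
    "young": {
        "name": "young",
        "description": (
            "Young running cohort (ages 18-26). Printed subgroup values for "
            "20 variables; all others inherit the general fixture."
        ),
        "groups": {
            "male": {"n": 16, "age_strata": [[16, 18.0, 26.0]]},
            "female": {"n": 40, "age_strata": [[40, 18.0, 26.0]]},
        },
        "variables": build_variables(YOUNG_PRINTED, inherit=general_vars),
    },
    "older": {
        "name": "older",
        "description": (
            "Older running cohort (ages 55-72). Printed subgroup values for "
            "12 variables; all others inherit the general fixture."
        ),
        "groups": {
            "male": {"n": 34, "age_strata": [[34, 55.0, 72.0]]},
            "female": {"n": 17, "age_strata": [[17, 55.0, 72.0]]},
        },
        "variables": build_variables(OLDER_PRINTED, inherit=general_vars),
    },
}

outdir = Path(__file__).resolve().parents[1] / "src" / "gaitsep" / "fixtures"
outdir.mkdir(parents=True, exist_ok=True)
for name, fx in fixtures.items():
    assert set(fx["variables"]) == set(VARIABLE_NAMES)
    path = outdir / f"{name}.json"
    path.write_text(json.dumps(fx, indent=1) + "\n")
    print(path, path.stat().st_size, "bytes")
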