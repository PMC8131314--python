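"""Build and validate a personalized EMA study design.

A design is the 13-item fixed battery plus up to 3 personalized complaint
items and up to 5 personal factors (26 items maximum), with prompts every
3 hours during the participant's waking window.
"""

import emadyn as ed
from emadyn.ema_design import default_fixed_items, format_clock

complaints = [ed.ItemSpec("headache", "How bad is your headache?", block="complaint")]
personal = [ed.ItemSpec("food_intake", "How well have you been eating?", block="personal")]
items = ed.personalize_question_set(default_fixed_items(), complaints, personal)

design = ed.StudyDesign(
    subject_id="p001", waking_start="08:00", waking_end="22:59", items=items
)
print("violations:", ed.validate_design(design))  # [] -> the design is valid
print("items:", len(items), "(13 fixed + 1 complaint + 1 personal, cap 26)")

schedule = ed.build_prompt_schedule(design)
print("prompts/day:", schedule.per_day_count, "| total sent:", len(schedule))
print("first day:", [format_clock(m) for m in schedule.clock_minutes[:schedule.per_day_count]])
# Five prompts per day, every 3 h from 08:00 -> the protocol's nominal density.
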