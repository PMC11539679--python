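"""Encode a 10-second episode, fuse it, and decode a fused value.

Builds the worked-example episode (baby on table seconds 1-9, drying 1-3,
stimulation 4-7, ventilation 5-9), encodes each activity with the periodic
generator G_e(i) = 2**i - 1, fuses per second by addition, and decodes one
fused value back into the exact set of simultaneous activities.
"""

from resuskit import ActivityProfile, decode_value, encode_episode, fuse, table3_fixture

profile = ActivityProfile(
    name="SUS4",
    activities=("baby on table", "drying", "stimulation", "ventilation"),
    acronyms=("BOT", "Dry", "Stim", "Vent"),
)

episode = table3_fixture()
code_matrix = encode_episode(episode, profile, n_seconds=10)

for i, activity in enumerate(profile.activities):
    print(f"g_{i + 1} ({activity:>13s}): {code_matrix.values[i].tolist()}")

fused = fuse(code_matrix)
print(f"fused x_j          : {fused.tolist()}")

# every fused value identifies one exact activity combination
second = 5
members = sorted(decode_value(int(fused[second - 1]), profile.H))
names = [profile.activities[i - 1] for i in members]
print(f"second {second}: fused value {fused[second - 1]} decodes to {names}")
# -> the code 23 = 1 + 7 + 15 can only mean table + stimulation + ventilation
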