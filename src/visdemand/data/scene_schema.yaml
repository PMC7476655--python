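# Scene-coding schema: 14 categorical classifiers applied to each snapshot.
version: 1
classifiers:
  - name: duration
    categories: [ad hoc, short, medium, long]
  - name: location
    categories: [indoors, outdoors]
  - name: familiarity
    categories: [home, public, work, school]
  - name: light_type
    categories: [artificial, natural, mixed, backlit, other]
  - name: brightness
    categories: [low, medium, bright]
  - name: object_distance
    categories: [within reach, short, medium, long]
  - name: focus_plane
    categories: [single, multiple]
  - name: periphery
    categories: [none, side, bottom, both]
  - name: scanning
    categories: ["yes", "no"]
  - name: hands
    categories: [none, 1 hand, 2 hands]
  - name: walking
    categories: ["yes", "no"]
  - name: coping_strategy_used
    categories: ["yes", "no"]
  - name: able_alone
    categories: ["yes", "no"]
  - name: time_of_day
    categories: ["6-12", "12-18", "18-24", "0-6"]
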