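# Task vocabulary: the 48-item visual-functioning questionnaire inventory
# (as adapted for observed activities; item wording is provisional and
# editable) plus bespoke labels observed in recordings that fall outside
# the 48-item instrument.
version: 1
provisional: true
vfq48:
  - Adjust to light changes
  - Avoid bumping into things and tripping
  - Clean the house and other household chores
  - Cross street
  - Do yard work, DIY, and maintenance
  - Eat and drink neatly
  - Find public restrooms
  - Find something on a crowded shelf
  - Fix a snack or a drink
  - Get around in unfamiliar places
  - Get around indoors in places you know
  - Get around outdoors in places you know
  - Go down/up steps
  - Go out at night
  - Go to the movies
  - Groom yourself
  - Handle finances
  - Identify food on a plate
  - Identify medicine
  - Identify money
  - Match clothes
  - Physically get dressed
  - Play sports and exercise
  - Play table and card games
  - Prepare meals
  - Read books
  - Read documents
  - Read mail and cards
  - Read maps
  - Read menus
  - Read newspaper and magazine headlines
  - Read newspaper or magazine articles
  - Read notices
  - Read other
  - Read package labels
  - Read recipes
  - Read signs
  - Read street signs and store names
  - Read writing
  - Recognize people from across the room
  - Recognize people up close
  - See photographs
  - Sign your name
  - Tell time
  - Use appliance dials, buttons, and remotes
  - Use public transportation
  - Watch TV
  - Work on your favorite hobby
bespoke:
  - ATM and other self-service machines
  - Appreciate environment
  - Other
  - Read print on TV
  - Read timetables
  - Search visually
  - Use PC
  - Use portable electronic devices
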