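city,n_tweets,n_users
"Albuquerque, New Mexico",839,224
"Atlanta, Georgia",4936,1739
"Baltimore, Maryland",2521,684
"Colorado Springs, Colorado",847,268
"Dallas, Texas",2472,782
"Fresno, California",421,153
"Kansas City, Missouri",1651,532
"Las Vegas, Nevada",2336,872
"Long Beach, California",17303,5189
"Louisville, Kentucky",1246,406
"Mesa, Arizona",1888,616
"Miami, Florida",2576,1080
"Milwaukee, Wisconsin",1578,388
"Minneapolis, Minnesota",1282,471
"New Orleans, Louisiana",2144,641
"Oakland, California",2601,614
"Oklahoma City, Oklahoma",1143,371
"Omaha, Nebraska",742,198
"Portland, Oregon",5528,928
"Raleigh, North Carolina",1588,454
"Sacramento, California",1721,565
"Tucson, Arizona",794,250
"Tulsa, Oklahoma",622,209
"Virginia Beach, Virginia",960,212
"Wichita, Kansas",435,132
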