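state_fips,abbr,name,region
09,CT,Connecticut,Northeast
23,ME,Maine,Northeast
25,MA,Massachusetts,Northeast
33,NH,New Hampshire,Northeast
44,RI,Rhode Island,Northeast
50,VT,Vermont,Northeast
34,NJ,New Jersey,Northeast
36,NY,New York,Northeast
42,PA,Pennsylvania,Northeast
17,IL,Illinois,Midwest
18,IN,Indiana,Midwest
26,MI,Michigan,Midwest
39,OH,Ohio,Midwest
55,WI,Wisconsin,Midwest
19,IA,Iowa,Midwest
20,KS,Kansas,Midwest
27,MN,Minnesota,Midwest
29,MO,Missouri,Midwest
31,NE,Nebraska,Midwest
38,ND,North Dakota,Midwest
46,SD,South Dakota,Midwest
10,DE,Delaware,South
11,DC,District of Columbia,South
12,FL,Florida,South
13,GA,Georgia,South
24,MD,Maryland,South
37,NC,North Carolina,South
45,SC,South Carolina,South
51,VA,Virginia,South
54,WV,West Virginia,South
01,AL,Alabama,South
21,KY,Kentucky,South
28,MS,Mississippi,South
47,TN,Tennessee,South
05,AR,Arkansas,South
22,LA,Louisiana,South
40,OK,Oklahoma,South
48,TX,Texas,South
04,AZ,Arizona,West
08,CO,Colorado,West
16,ID,Idaho,West
30,MT,Montana,West
32,NV,Nevada,West
35,NM,New Mexico,West
49,UT,Utah,West
56,WY,Wyoming,West
06,CA,California,West
41,OR,Oregon,West
53,WA,Washington,West
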