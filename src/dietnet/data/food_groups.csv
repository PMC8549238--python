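index,group
1,Red meat
2,Processed meat
3,Organ meat
4,Fish
5,Low-fat dairy
6,High-fat dairy
7,Fresh fruit
8,Dried fruit
9,Canned fruit
10,Fruit juices
11,Raw vegetables
12,Cooked vegetables
13,Cabbages
14,Garlic
15,Mushroom
16,Other vegetables
17,Potatoes
18,Side dish
19,Grains
20,Nuts
21,Legumes
22,Snacks
23,Salty snacks
24,Cookies/cake
25,Pickles and flavors
26,Chips/puff
27,Sugar sweetened beverages
28,Sauces
29,Butter
30,Margarine
31,Animal fat
32,Vegetable oils
33,Egg
34,Tea
35,Coffee
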