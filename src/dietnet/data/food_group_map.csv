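item_id,item_label,group_label
1,sugar,Sugar and sweets
2,chocolate powder,Sugar and sweets
3,homemade sweets,Sugar and sweets
4,industrialized sweets,Sugar and sweets
5,stuffed biscuit,Sugar and sweets
6,candies,Sugar and sweets
7,chewing gum and lollipops,Sugar and sweets
8,chocolate bar,Sugar and sweets
9,gelatin,Sugar and sweets
10,ice cream and popsicle,Sugar and sweets
11,soda (normal or diet/light),Sweetened beverages
12,artificial juice,Sweetened beverages
13,carbonated drinks,Sweetened beverages
14,artificial refreshment,Sweetened beverages
15,energy drink,Sweetened beverages
16,liquid or powdered sweetener,Sweetened beverages
17,acaraje and abara,Typical Brazilian dishes
18,vatapa,Typical Brazilian dishes
19,caruru,Typical Brazilian dishes
20,feijoada,Typical Brazilian dishes
21,dobradinha,Typical Brazilian dishes
22,feijao tropeiro,Typical Brazilian dishes
23,coconut milk,Typical Brazilian dishes
24,moqueca,Typical Brazilian dishes
25,fried potatoes,Fast food
26,potato chips,Fast food
27,pizza,Fast food
28,lasagna,Fast food
29,ketchup,Fast food
30,ready-made soups,Fast food
31,sandwich,Fast food
32,industrialized salty snack,Fast food
33,instant noodles,Fast food
34,butter,Oils
35,margarine,Oils
36,vegetable oil,Oils
37,mayonnaise,Oils
38,olive oil,Oils
39,palm oil,Oils
40,whole milk (powder or liquid),Milk and dairy
41,skimmed milk (powder or liquid),Milk and dairy
42,fermented milk,Milk and dairy
43,yogurt,Milk and dairy
44,chocolate milk drink,Milk and dairy
45,yellow cheese,Milk and dairy
46,white cheese,Milk and dairy
47,cream cheese,Milk and dairy
48,creamy curd,Milk and dairy
49,bovine meat (fried or cooked),Meat
50,chicken (fried or cooked),Meat
51,fish (fried or cooked),Meat
52,seafood,Meat
53,viscera,Meat
54,chicken egg,Meat
55,jerky beef,Meat
56,ham,Processed meat products
57,mortadella,Processed meat products
58,sausage,Processed meat products
59,calabrese,Processed meat products
60,bread (white or whole),Rice and cereals
61,rice (white or whole),Rice and cereals
62,noodles (white or whole),Rice and cereals
63,cassava flour,Rice and cereals
64,farinaceous (oats or wheat germ),Rice and cereals
65,green corn or corn couscous,Rice and cereals
66,salted popcorn,Rice and cereals
67,homemade or box cake,Rice and cereals
68,granola,Rice and cereals
69,biscuit (salted or sweet),Rice and cereals
70,pasta soup,Rice and cereals
71,cassava,Roots
72,sweet potato,Roots
73,potato,Roots
74,beans,Beans and legumes
75,peanuts,Beans and legumes
76,nuts and walnuts,Beans and legumes
77,lettuce,Vegetables
78,cabbage,Vegetables
79,pumpkin,Vegetables
80,carrot,Vegetables
81,tomato,Vegetables
82,chayote,Vegetables
83,okra,Vegetables
84,vegetable salad,Vegetables
85,pineapple,Fruits
86,avocado,Fruits
87,banana,Fruits
88,jackfruit,Fruits
89,papaya,Fruits
90,mango,Fruits
91,apple,Fruits
92,watermelon,Fruits
93,orange,Fruits
94,tangerine,Fruits
95,fruit juice or fruit pulp,Fruits
96,coffee,Coffee
97,tea,Coffee
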